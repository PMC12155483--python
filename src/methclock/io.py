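"""Readers, writers and containers for targeted bisulfite-sequencing data.

The central container is the :class:`PatternSet`: per-read CpG methylation
state vectors ("epireads") anchored to the reference CpG coordinates of a
small panel of target regions.  Everything downstream — beta values,
within-sample heterogeneity scores, clock features — is computed from it.

Coordinates are 0-based half-open throughout.  A CpG is identified by the
position of its C on the forward strand; calls from reads aligned to the
reverse (bottom) bisulfite strand are collapsed onto that coordinate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum span (last C minus first C, bp) of a 5-CpG stretch for a region
#: to be considered eligible for heterogeneity-based clock design.
ELIGIBILITY_SPAN_BP = 150
ELIGIBILITY_MIN_CPGS = 5

_STATES_RE = re.compile(r"^[MU]+$")


class FormatError(ValueError):
    """Raised for malformed input files (BED, TSV, alignment records)."""


@dataclass(frozen=True)
class TargetRegion:
    """A target amplicon with its reference CpG positions.

    ``cpg_positions`` holds the forward-strand C coordinate of every CpG in
    the region, strictly increasing, all within ``[start, end)``.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval for region {self.region_id!r}")
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"cpg_positions not strictly increasing in {self.region_id!r}")
        if pos and (pos[0] < self.start or pos[-1] >= self.end):
            raise ValueError(f"cpg_positions outside [start,end) in {self.region_id!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def eligible(self) -> bool:
        """True if the region carries >=5 CpGs within a 150 bp span.

        This is the design rule for loci usable with read-level
        heterogeneity scores under short paired-end amplicon sequencing.
        """
        return region_is_eligible(self.cpg_positions)

    def cpg_ids(self) -> list[str]:
        return [f"{self.region_id}:{p}" for p in self.cpg_positions]


def region_is_eligible(
    cpg_positions: Sequence[int],
    min_cpgs: int = ELIGIBILITY_MIN_CPGS,
    span_bp: int = ELIGIBILITY_SPAN_BP,
) -> bool:
    """Check for a stretch of ``min_cpgs`` consecutive CpGs spanning <= ``span_bp``."""
    pos = list(cpg_positions)
    if len(pos) < min_cpgs:
        return False
    k = min_cpgs - 1
    return any(pos[i + k] - pos[i] <= span_bp for i in range(len(pos) - k))


@dataclass
class SampleRecord:
    """One row of the sample sheet.

    Either ``passage`` (culture passage number) or ``donor_age`` (years) may
    be missing (``None``); samples missing both are flagged but retained.
    """

    sample_id: str
    passage: int | None = None
    donor_age: float | None = None
    group: str = ""

    @property
    def has_target(self) -> bool:
        return self.passage is not None or self.donor_age is not None


@dataclass(frozen=True)
class ReadPattern:
    """The methylation states of one read over consecutive covered CpGs.

    ``states`` is a string over {M, U}; position ``i`` of the string refers
    to CpG index ``first_cpg_index + i`` of the region's CpG list.
    """

    sample_id: str
    region_id: str
    first_cpg_index: int
    states: str

    def __post_init__(self) -> None:
        if self.first_cpg_index < 0:
            raise ValueError("first_cpg_index must be >= 0")
        if not _STATES_RE.match(self.states):
            raise FormatError(f"states must be non-empty over {{M,U}}, got {self.states!r}")

    @property
    def cpg_indices(self) -> range:
        return range(self.first_cpg_index, self.first_cpg_index + len(self.states))

    def state_at(self, cpg_index: int) -> str | None:
        off = cpg_index - self.first_cpg_index
        if 0 <= off < len(self.states):
            return self.states[off]
        return None


class PatternSet:
    """Read patterns grouped by (sample, region), plus the region panel."""

    def __init__(self, regions: Sequence[TargetRegion], reads: Iterable[ReadPattern] = ()) -> None:
        self.regions: list[TargetRegion] = list(regions)
        self._by_region: dict[str, TargetRegion] = {r.region_id: r for r in self.regions}
        if len(self._by_region) != len(self.regions):
            raise ValueError("duplicate region_id in region panel")
        self._reads: dict[tuple[str, str], list[ReadPattern]] = {}
        for rp in reads:
            self.add(rp)

    def add(self, rp: ReadPattern) -> None:
        region = self._by_region.get(rp.region_id)
        if region is None:
            raise ValueError(f"ReadPattern references unknown region {rp.region_id!r}")
        if rp.first_cpg_index + len(rp.states) > region.n_cpgs:
            raise ValueError(
                f"pattern exceeds CpG count of region {rp.region_id!r} "
                f"({rp.first_cpg_index}+{len(rp.states)} > {region.n_cpgs})"
            )
        self._reads.setdefault((rp.sample_id, rp.region_id), []).append(rp)

    def region(self, region_id: str) -> TargetRegion:
        return self._by_region[region_id]

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self._reads})

    def reads_for(self, sample_id: str, region_id: str) -> list[ReadPattern]:
        return self._reads.get((sample_id, region_id), [])

    def n_reads(self, sample_id: str | None = None, region_id: str | None = None) -> int:
        total = 0
        for (s, r), lst in self._reads.items():
            if (sample_id is None or s == sample_id) and (region_id is None or r == region_id):
                total += len(lst)
        return total

    def __iter__(self):
        for key in sorted(self._reads):
            yield from self._reads[key]

    def __len__(self) -> int:
        return sum(len(v) for v in self._reads.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatternSet):
            return NotImplemented
        if self.regions != other.regions:
            return False
        if set(self._reads) != set(other._reads):
            return False
        return all(
            sorted(self._reads[k], key=_read_sort_key) == sorted(other._reads[k], key=_read_sort_key)
            for k in self._reads
        )


def _read_sort_key(rp: ReadPattern) -> tuple:
    return (rp.sample_id, rp.region_id, rp.first_cpg_index, rp.states)


# ---------------------------------------------------------------------------
# Region loading


def find_cpgs(sequence: str, start: int = 0) -> list[int]:
    """Forward-strand C positions of every CG dinucleotide in ``sequence``.

    Positions are offset by ``start`` so they are reference coordinates when
    ``sequence`` is a slice beginning at ``start``.
    """
    seq = sequence.upper()
    return [start + m.start() for m in re.finditer("CG", seq)]


def load_regions(
    path: str | Path,
    fasta: str | Path | None = None,
    cpg_positions: Mapping[str, Sequence[int]] | None = None,
) -> list[TargetRegion]:
    """Load target regions from a 4-column BED file.

    CpG positions are discovered by scanning the FASTA reference for ``CG``
    on the forward strand within each interval, or taken from an explicit
    per-region mapping ``cpg_positions`` (region_id -> positions).  Regions
    with zero CpGs are retained (with a warning) but are ineligible for
    heterogeneity analysis.
    """
    if (fasta is None) == (cpg_positions is None):
        raise ValueError("provide exactly one of fasta or cpg_positions")
    ref = None
    if fasta is not None:
        import pyfaidx

        ref = pyfaidx.Fasta(str(fasta))

    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line needs 4 columns (chrom start end name)")
            chrom, s, e, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if ref is not None:
                seq = ref[chrom][start:end].seq
                positions = find_cpgs(seq, start=start)
            else:
                positions = sorted(int(p) for p in cpg_positions.get(name, ()))
            if not positions:
                logger.warning("region %s has 0 CpGs; retained but ineligible", name)
            regions.append(TargetRegion(name, chrom, start, end, tuple(positions)))
    return regions


# ---------------------------------------------------------------------------
# Sample sheet


def load_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a TSV sample sheet with columns sample_id/passage/donor_age/group."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet must contain columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dups}")
    records = []
    for _, row in df.iterrows():
        passage = row.get("passage")
        age = row.get("donor_age")
        passage = None if pd.isna(passage) else int(passage)
        age = None if pd.isna(age) else float(age)
        group = row.get("group")
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            passage=passage,
            donor_age=age,
            group="" if pd.isna(group) else str(group),
        )
        if not rec.has_target:
            logger.warning("sample %s has neither passage nor donor_age", rec.sample_id)
        records.append(rec)
    return records


def sample_sheet_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "passage": [s.passage for s in samples],
            "donor_age": [s.donor_age for s in samples],
            "group": [s.group for s in samples],
        }
    ).set_index("sample_id")


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    sample_sheet_to_frame(samples).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment extraction (Bismark convention)


def _bismark_forward_c(rpos: int, xg: str) -> int:
    # On the original-bottom strand (XG == GA) the CpG call sits on the G of
    # the forward strand; collapse to the forward-strand C one base left.
    return rpos - 1 if xg == "GA" else rpos


def extract_patterns_from_alignments(
    paths: Mapping[str, str | Path],
    regions: Sequence[TargetRegion],
    merge_mates: bool = True,
) -> PatternSet:
    """Extract read-level CpG patterns from Bismark-style alignments.

    ``paths`` maps sample_id to a SAM/BAM/CRAM file whose reads carry the
    Bismark ``XM`` methylation-call string ('Z' methylated CpG, 'z'
    unmethylated; other contexts ignored) and the ``XG`` bisulfite-strand
    tag.  Paired mates sharing a name are merged into one pattern; where
    overlapping mates disagree the higher-base-quality call wins (tie: mate
    1).  A read whose covered CpGs are interrupted by a gap over a listed
    CpG is split into separate patterns at the gap.
    """
    import pysam

    ps = PatternSet(regions)
    index = _build_cpg_index(regions)
    skipped = 0
    for sample_id, path in paths.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            # per (qname, region): cpg_index -> (state, qual, mate_rank)
            pending: dict[tuple[str, str], dict[int, tuple[str, int, int]]] = {}
            for read in af:
                if read.is_unmapped or read.query_sequence is None:
                    continue
                calls = _read_cpg_calls(read, index)
                if calls is None:
                    skipped += 1
                    continue
                mate_rank = 1 if read.is_read2 else 0
                for region_id, cpg_index, state, qual in calls:
                    key = (read.query_name, region_id) if merge_mates else (
                        f"{read.query_name}/{mate_rank}", region_id)
                    slot = pending.setdefault(key, {})
                    prev = slot.get(cpg_index)
                    if prev is None or (qual, -mate_rank) > (prev[1], -prev[2]):
                        slot[cpg_index] = (state, qual, mate_rank)
            for (qname, region_id), slot in sorted(pending.items()):
                sid = str(sample_id)
                for rp in _calls_to_patterns(sid, region_id, slot):
                    ps.add(rp)
    if skipped:
        logger.info("skipped %d reads overlapping no target CpG", skipped)
    return ps


def _build_cpg_index(regions: Sequence[TargetRegion]) -> dict[tuple[str, int], tuple[str, int]]:
    """(chrom, forward C position) -> (region_id, cpg index)."""
    out: dict[tuple[str, int], tuple[str, int]] = {}
    for region in regions:
        for i, pos in enumerate(region.cpg_positions):
            out[(region.chrom, pos)] = (region.region_id, i)
    return out


def _read_cpg_calls(read, index) -> list[tuple[str, int, str, int]] | None:
    """Per-read list of (region_id, cpg_index, state, qual); None if no target CpG."""
    try:
        xm = read.get_tag("XM")
    except KeyError as exc:
        raise FormatError(f"read {read.query_name!r} lacks the XM methylation-call tag") from exc
    try:
        xg = read.get_tag("XG")
    except KeyError:
        xg = "GA" if read.is_reverse else "CT"
    quals = read.query_qualities
    chrom = read.reference_name
    out: list[tuple[str, int, str, int]] = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        call = xm[qpos]
        if call not in ("z", "Z"):
            continue
        fwd_c = _bismark_forward_c(rpos, xg)
        hit = index.get((chrom, fwd_c))
        if hit is None:
            continue
        region_id, cpg_index = hit
        state = "M" if call == "Z" else "U"
        qual = int(quals[qpos]) if quals is not None else 0
        out.append((region_id, cpg_index, state, qual))
    return out or None


def _calls_to_patterns(
    sample_id: str, region_id: str, slot: Mapping[int, tuple[str, int, int]]
) -> list[ReadPattern]:
    """Turn a sparse cpg_index -> call map into contiguous ReadPatterns."""
    patterns = []
    indices = sorted(slot)
    run_start = 0
    for k in range(1, len(indices) + 1):
        if k == len(indices) or indices[k] != indices[k - 1] + 1:
            run = indices[run_start:k]
            states = "".join(slot[i][0] for i in run)
            patterns.append(ReadPattern(sample_id, region_id, run[0], states))
            run_start = k
    return patterns


# ---------------------------------------------------------------------------
# Pattern TSV round trip

_PATTERN_COLUMNS = ["sample_id", "region_id", "first_cpg_index", "states"]


def patterns_to_tsv(ps: PatternSet, path: str | Path) -> None:
    rows = [(rp.sample_id, rp.region_id, rp.first_cpg_index, rp.states) for rp in ps]
    pd.DataFrame(rows, columns=_PATTERN_COLUMNS).to_csv(path, sep="\t", index=False)


def patterns_from_tsv(path: str | Path, regions: Sequence[TargetRegion]) -> PatternSet:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "region_id": str, "states": str}
    )
    missing = set(_PATTERN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pattern TSV missing columns {sorted(missing)}")
    ps = PatternSet(regions)
    for row in df.itertuples(index=False):
        states = str(row.states)
        if not _STATES_RE.match(states):
            raise FormatError(f"invalid states string {states!r} in {path}")
        ps.add(ReadPattern(str(row.sample_id), str(row.region_id), int(row.first_cpg_index), states))
    return ps


def write_regions_bed(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def write_cpg_positions(regions: Sequence[TargetRegion], path: str | Path) -> None:
    """Companion TSV giving each region's CpG coordinates explicitly."""
    rows = [(r.region_id, p) for r in regions for p in r.cpg_positions]
    pd.DataFrame(rows, columns=["region_id", "position"]).to_csv(path, sep="\t", index=False)


def read_cpg_positions(path: str | Path) -> dict[str, list[int]]:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    out: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.region_id), []).append(int(row.position))
    return out


# ---------------------------------------------------------------------------
# Beta values


@dataclass
class BetaMatrix:
    """Samples x CpGs mean-methylation matrix with a parallel coverage matrix.

    ``values`` are methylated-read fractions in [0,1]; entries with coverage
    below the configured minimum are NaN (missing, never zero-filled).
    """

    values: pd.DataFrame
    coverage: pd.DataFrame
    min_coverage: int = 1

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")
        cov_path = Path(path).with_suffix(".coverage.tsv")
        self.coverage.to_csv(cov_path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, min_coverage: int = 1) -> "BetaMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        cov_path = Path(path).with_suffix(".coverage.tsv")
        if cov_path.exists():
            coverage = pd.read_csv(cov_path, sep="\t", index_col=0)
        else:
            coverage = values.notna().astype(int) * min_coverage
        return cls(values, coverage, min_coverage)


def compute_beta(ps: PatternSet, min_coverage: int = 10) -> BetaMatrix:
    """Per-CpG mean methylation: methylated reads / covering reads.

    Entries with fewer than ``min_coverage`` covering reads are NaN; the
    observed coverage is still recorded.
    """
    cpg_ids: list[str] = []
    col_of: dict[tuple[str, int], int] = {}
    for region in ps.regions:
        for i, cid in enumerate(region.cpg_ids()):
            col_of[(region.region_id, i)] = len(cpg_ids)
            cpg_ids.append(cid)
    samples = ps.sample_ids
    meth = np.zeros((len(samples), len(cpg_ids)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for si, sample in enumerate(samples):
        for region in ps.regions:
            for rp in ps.reads_for(sample, region.region_id):
                base = col_of[(region.region_id, rp.first_cpg_index)]
                for off, state in enumerate(rp.states):
                    cov[si, base + off] += 1
                    if state == "M":
                        meth[si, base + off] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = meth / cov
    beta[cov < min_coverage] = np.nan
    values = pd.DataFrame(beta, index=pd.Index(samples, name="sample_id"), columns=cpg_ids)
    coverage = pd.DataFrame(cov, index=values.index, columns=cpg_ids)
    return BetaMatrix(values, coverage, min_coverage)
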