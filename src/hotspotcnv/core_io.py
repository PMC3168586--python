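"""Domain types and file I/O for the hotspot-CNV pipeline.

Internal coordinates are 1-based inclusive, matching how aCGH calls are
conventionally printed (chr16: 73,290,945-73,626,825).  All BED-style I/O
converts to and from 0-based half-open coordinates at the file boundary.
Chromosome names are normalized to the ``chr`` prefix on read.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RegionClass",
    "Probe",
    "ProbeDesign",
    "ValueKind",
    "SampleProfile",
    "CopyState",
    "CnvCall",
    "ControlCatalog",
    "BurdenTable",
    "interval_length",
    "normalize_chrom",
    "chrom_sort_key",
    "read_probe_design",
    "write_probe_design",
    "read_logratio_table",
    "write_logratio_table",
    "read_cnv_bed",
    "write_cnv_bed",
    "read_control_catalog",
    "write_control_catalog",
]


class FormatError(ValueError):
    """A file record violates the expected format or a type invariant."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome label to the ``chr`` prefix ("1" -> "chr1")."""
    name = name.strip()
    if not name:
        raise FormatError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


_CHROM_NUM = re.compile(r"^chr(\d+)$")


def chrom_sort_key(chrom: str):
    """Sort key placing chr1..chr22 numerically before chrX/chrY/others."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise FormatError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise FormatError(
                f"interval end {self.end} < start {self.start} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(shared/len(self), shared/len(other)); 0 when disjoint."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bases of a 1-based inclusive interval (end - start + 1)."""
    return iv.length


class RegionClass(str, enum.Enum):
    HOTSPOT = "hotspot"
    BACKBONE = "backbone"


@dataclass(frozen=True)
class Probe:
    probe_id: str
    interval: GenomicInterval
    region_class: RegionClass


class ProbeDesign:
    """An ordered, validated set of array probes.

    Probes are stored sorted by (chromosome, start); probes on the same
    chromosome must not overlap and probe ids must be unique.  Column
    arrays aligned to probe order are exposed for vectorized access, and
    per-chromosome contiguous index slices via :meth:`chrom_slices`.
    """

    def __init__(
        self,
        probes: Sequence[Probe],
        hotspot_regions: Sequence[GenomicInterval] = (),
    ):
        probes = sorted(
            probes, key=lambda p: (chrom_sort_key(p.interval.chrom), p.interval.start)
        )
        ids = [p.probe_id for p in probes]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise FormatError(f"duplicate probe id {dup!r}")
        for a, b in zip(probes, probes[1:]):
            if (
                a.interval.chrom == b.interval.chrom
                and b.interval.start <= a.interval.end
            ):
                raise FormatError(
                    f"overlapping probes {a.probe_id!r} and {b.probe_id!r} "
                    f"on {a.interval.chrom}"
                )
        self.probes: tuple[Probe, ...] = tuple(probes)
        if not hotspot_regions:
            hotspot_regions = self._regions_from_probe_classes(probes)
        self.hotspot_regions: tuple[GenomicInterval, ...] = tuple(hotspot_regions)
        self.probe_ids: tuple[str, ...] = tuple(p.probe_id for p in probes)
        self.chroms: np.ndarray = np.array(
            [p.interval.chrom for p in probes], dtype=object
        )
        self.starts: np.ndarray = np.array(
            [p.interval.start for p in probes], dtype=np.int64
        )
        self.ends: np.ndarray = np.array(
            [p.interval.end for p in probes], dtype=np.int64
        )
        self._id_index = {pid: i for i, pid in enumerate(self.probe_ids)}

    @staticmethod
    def _regions_from_probe_classes(
        probes: Sequence[Probe],
    ) -> list[GenomicInterval]:
        """Reconstruct hotspot regions as maximal runs of hotspot probes."""
        regions: list[GenomicInterval] = []
        run_start: GenomicInterval | None = None
        run_end: GenomicInterval | None = None
        for p in probes:
            if p.region_class is RegionClass.HOTSPOT:
                if run_start is not None and p.interval.chrom == run_start.chrom:
                    run_end = p.interval
                else:
                    if run_start is not None:
                        regions.append(
                            GenomicInterval(
                                run_start.chrom, run_start.start, run_end.end
                            )
                        )
                    run_start = run_end = p.interval
            else:
                if run_start is not None:
                    regions.append(
                        GenomicInterval(run_start.chrom, run_start.start, run_end.end)
                    )
                    run_start = run_end = None
        if run_start is not None:
            regions.append(
                GenomicInterval(run_start.chrom, run_start.start, run_end.end)
            )
        return regions

    def __len__(self) -> int:
        return len(self.probes)

    def index_of(self, probe_id: str) -> int:
        return self._id_index[probe_id]

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in design order."""
        out: dict[str, slice] = {}
        if len(self) == 0:
            return out
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chroms[i] != self.chroms[start]:
                out[str(self.chroms[start])] = slice(start, i)
                start = i
        return out


class ValueKind(str, enum.Enum):
    LOG2_RATIO = "log2_ratio"
    Z_SCORE = "z_score"


@dataclass
class SampleProfile:
    """A per-probe signal vector for one sample, aligned to a ProbeDesign."""

    sample_id: str
    values: np.ndarray
    value_kind: ValueKind

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("profile values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(
                f"non-finite value in profile for sample {self.sample_id!r}"
            )


class CopyState(enum.Enum):
    DECREASED = "decreased"
    NORMAL = "normal"
    INCREASED = "increased"


@dataclass(frozen=True)
class CnvCall:
    """A contiguous non-normal copy-number segment in one sample."""

    sample_id: str
    interval: GenomicInterval
    state: CopyState
    n_probes: int
    mean_z: float

    def __post_init__(self):
        if self.state is CopyState.NORMAL:
            raise FormatError("a CNV call cannot be in the normal state")
        if self.n_probes < 1:
            raise FormatError("a CNV call must cover at least one probe")
        if self.state is CopyState.DECREASED and not self.mean_z < 0:
            raise FormatError(
                f"decreased call with non-negative mean z ({self.mean_z})"
            )
        if self.state is CopyState.INCREASED and not self.mean_z > 0:
            raise FormatError(
                f"increased call with non-positive mean z ({self.mean_z})"
            )

    @property
    def size_bp(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class ControlCatalog:
    """CNV intervals observed in a control cohort, with carrier counts."""

    cohort_size: int
    records: tuple[tuple[GenomicInterval, int], ...]

    def __post_init__(self):
        if self.cohort_size <= 0:
            raise FormatError("control cohort size must be positive")
        recs = tuple(
            sorted(self.records, key=lambda r: (chrom_sort_key(r[0].chrom), r[0].start))
        )
        for iv, count in recs:
            if not 0 <= count <= self.cohort_size:
                raise FormatError(
                    f"carrier count {count} outside [0, {self.cohort_size}] "
                    f"for {iv.chrom}:{iv.start}-{iv.end}"
                )
        object.__setattr__(self, "records", recs)


@dataclass(frozen=True)
class BurdenTable:
    """2x2 carrier/non-carrier counts for cases vs controls."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self):
        for v in (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        ):
            if v < 0:
                raise FormatError("burden table counts must be non-negative")
        if self.case_carriers + self.case_noncarriers <= 0:
            raise FormatError("no cases in burden table")
        if self.control_carriers + self.control_noncarriers <= 0:
            raise FormatError("no controls in burden table")

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _write_header(fh, header: dict | None):
    if header:
        for key, value in header.items():
            fh.write(f"#{key}={value}\n")


def read_probe_design(path) -> ProbeDesign:
    """Read a BED5 probe design (chrom, start, end, name, region class).

    Input coordinates are 0-based half-open and converted to the internal
    1-based inclusive frame.  Unsorted input is sorted with a warning;
    duplicate probe ids and malformed lines are errors.
    """
    path = Path(path)
    probes: list[Probe] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        chrom, start_s, end_s, name, klass = fields[:5]
        try:
            bed_start, bed_end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if bed_end <= bed_start:
            raise FormatError(f"{path}:{lineno}: empty or inverted interval")
        try:
            region = RegionClass(klass)
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: unknown region class {klass!r}"
            ) from exc
        iv = GenomicInterval(normalize_chrom(chrom), bed_start + 1, bed_end)
        probes.append(Probe(name, iv, region))
    if not probes:
        logger.warning("probe design %s is empty", path)
    keys = [(chrom_sort_key(p.interval.chrom), p.interval.start) for p in probes]
    if keys != sorted(keys):
        logger.warning("probe design %s was not sorted; sorting", path)
    return ProbeDesign(probes)


def write_probe_design(design: ProbeDesign, path, header: dict | None = None) -> None:
    """Write a probe design as BED5 (0-based half-open)."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        for p in design.probes:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start - 1}\t{p.interval.end}"
                f"\t{p.probe_id}\t{p.region_class.value}\n"
            )


def read_logratio_table(path, design: ProbeDesign) -> list[SampleProfile]:
    """Read a probe-by-sample log2-ratio TSV aligned to ``design``.

    Rows are matched to the design by probe id, so row order is free.
    Unknown probe ids and missing values are errors (no imputation).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")
    unknown = set(df["probe_id"]) - set(design.probe_ids)
    if unknown:
        raise FormatError(
            f"{path}: probe id(s) not in design: {sorted(unknown)[:5]}"
        )
    missing_rows = set(design.probe_ids) - set(df["probe_id"])
    if missing_rows:
        raise FormatError(
            f"{path}: design probes missing from table: {sorted(missing_rows)[:5]}"
        )
    df = df.set_index("probe_id").reindex(list(design.probe_ids))
    profiles = []
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            bad = df.index[np.isnan(col)][0]
            raise FormatError(
                f"{path}: missing or non-numeric value for probe {bad!r}, "
                f"sample {sample!r}"
            )
        profiles.append(SampleProfile(str(sample), col, ValueKind.LOG2_RATIO))
    return profiles


def write_logratio_table(
    profiles: Sequence[SampleProfile],
    design: ProbeDesign,
    path,
    header: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("probe_id\t" + "\t".join(p.sample_id for p in profiles) + "\n")
        matrix = np.column_stack([p.values for p in profiles])
        for i, pid in enumerate(design.probe_ids):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in matrix[i]) + "\n")


_CNV_COLUMNS = (
    "chrom start end sample_id score state n_probes mean_z".split()
)


def write_cnv_bed(calls: Sequence[CnvCall], path, header: dict | None = None) -> None:
    """Write calls as an 8-column BED-derived TSV (0-based half-open)."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("#" + "\t".join(_CNV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start - 1}\t{c.interval.end}"
                f"\t{c.sample_id}\t0\t{c.state.value}\t{c.n_probes}"
                f"\t{repr(float(c.mean_z))}\n"
            )


def read_cnv_bed(path) -> list[CnvCall]:
    path = Path(path)
    calls = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 8:
            raise FormatError(
                f"{path}:{lineno}: expected 8 fields, got {len(fields)}"
            )
        chrom, start_s, end_s, sample_id, _score, state_s, n_probes_s, mean_z_s = fields
        iv = GenomicInterval(normalize_chrom(chrom), int(start_s) + 1, int(end_s))
        calls.append(
            CnvCall(
                sample_id=sample_id,
                interval=iv,
                state=CopyState(state_s),
                n_probes=int(n_probes_s),
                mean_z=float(mean_z_s),
            )
        )
    return calls


def read_control_catalog(path) -> ControlCatalog:
    """Read a control-CNV TSV with a ``#cohort_size=<N>`` header line."""
    path = Path(path)
    cohort_size = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#cohort_size="):
                cohort_size = int(line.split("=", 1)[1])
                break
    if cohort_size is None:
        raise FormatError(f"{path}: missing '#cohort_size=<N>' header line")
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
            )
        chrom, start_s, end_s, count_s = fields[:4]
        iv = GenomicInterval(normalize_chrom(chrom), int(start_s) + 1, int(end_s))
        records.append((iv, int(count_s)))
    return ControlCatalog(cohort_size=cohort_size, records=tuple(records))


def write_control_catalog(catalog: ControlCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cohort_size={catalog.cohort_size}\n")
        for iv, count in catalog.records:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{count}\n")
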