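"""Genomic data model and file I/O.

Copy-number profiles are tab-separated tables with genomic bin coordinates
(0-based, half-open, BED convention) in the leading columns and one column of
relative copy numbers per patient.  Segments arrive as BED plus a two-column
segment-name -> chromosome-arm table; clinical outcomes as a TSV keyed by
patient id.  Decomposition results round-trip through a single ``.npz``
archive keyed by factor name, with TSV exports of every factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Malformed or inconsistent input data."""


_RESERVED_COLUMNS = ("chrom", "start", "end", "n_probes", "gc")


@dataclass(frozen=True)
class GenomicBin:
    """One genomic bin or probe footprint (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    n_probes: int = 1
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"bin {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.n_probes < 1:
            raise DataError(f"bin {self.chrom}:{self.start}-{self.end}: n_probes < 1")
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise DataError(
                f"bin {self.chrom}:{self.start}-{self.end}: gc_fraction outside [0, 1]"
            )


@dataclass
class ProfileMatrix:
    """Relative copy-number matrix: K genomic bins x L patients."""

    bins: list[GenomicBin]
    patients: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.patients)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.bins)} bins x {len(self.patients)} patients"
            )
        if len(set(self.patients)) != len(self.patients):
            dupes = sorted({p for p in self.patients if self.patients.count(p) > 1})
            raise DataError(f"duplicate patient identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at bin {bad[0]}, patient {self.patients[bad[1]]}; "
                "missing values are not supported"
            )

    @property
    def k(self) -> int:
        return len(self.bins)

    @property
    def l(self) -> int:
        return len(self.patients)

    def sorted_by_position(self) -> "ProfileMatrix":
        """Return a copy with bins sorted by (chrom, start); stable order."""
        order = sorted(
            range(self.k), key=lambda i: (self.bins[i].chrom, self.bins[i].start)
        )
        if order == list(range(self.k)):
            return self
        return ProfileMatrix(
            bins=[self.bins[i] for i in order],
            patients=list(self.patients),
            values=self.values[order, :],
        )

    def gc(self) -> np.ndarray | None:
        """Per-bin GC fractions, or None when any bin lacks one."""
        vals = [b.gc_fraction for b in self.bins]
        if any(v is None for v in vals):
            return None
        return np.asarray(vals, dtype=float)


@dataclass
class MatchedPair:
    """Patient-matched tumor (D1) and normal (D2) profile matrices.

    The two matrices share an ordered patient axis; their bin axes are
    independent (K1 may differ from K2).
    """

    tumor: ProfileMatrix
    normal: ProfileMatrix

    def __post_init__(self) -> None:
        if self.tumor.patients != self.normal.patients:
            raise DataError("tumor and normal patient axes differ; use match_patients")

    @property
    def patients(self) -> list[str]:
        return self.tumor.patients


@dataclass
class MatchedTensorPair:
    """Patient- and platform-matched third-order tensors (K_i x L x M)."""

    tumor: np.ndarray
    normal: np.ndarray
    patients: list[str]
    platforms: list[str]
    tumor_bins: list[GenomicBin] = field(default_factory=list)
    normal_bins: list[GenomicBin] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        l, m = len(self.patients), len(self.platforms)
        for name, t in (("tumor", self.tumor), ("normal", self.normal)):
            if t.ndim != 3 or t.shape[1:] != (l, m):
                raise DataError(
                    f"{name} tensor shape {t.shape} incompatible with "
                    f"L={l} patients, M={m} platforms"
                )
            if l * m > t.shape[0]:
                raise DataError(
                    f"{name} tensor needs L*M={l * m} <= K={t.shape[0]} rows"
                )


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    label: str
    arm: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(f"segment {self.label}: start must be < end")


@dataclass
class SegmentSet:
    """CBS-style segments, each assigned to exactly one chromosome arm."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        by_arm: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_arm.setdefault(seg.arm, []).append(seg)
        for arm, segs in by_arm.items():
            segs = sorted(segs, key=lambda s: (s.chrom, s.start))
            for a, b in zip(segs, segs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise DataError(
                        f"segments {a.label} and {b.label} overlap within arm {arm}"
                    )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class SurvivalRecord:
    """One patient's clinical outcome row."""

    patient_id: str
    os_months: float
    os_event: bool
    pfs_months: float | None = None
    stage: int | None = None
    platinum: bool | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise DataError(f"{self.patient_id}: os_months < 0")
        if self.pfs_months is not None and self.pfs_months < 0:
            raise DataError(f"{self.patient_id}: pfs_months < 0")


# ---------------------------------------------------------------------------
# profile matrices


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a profile TSV: ``chrom start end [n_probes] [gc] <patient...>``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    patient_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if len(patient_cols) != len(set(patient_cols)):
        raise DataError(f"{path}: duplicate patient id columns")
    has_np = "n_probes" in df.columns
    has_gc = "gc" in df.columns
    bins = []
    for i, row in df.iterrows():
        try:
            bins.append(
                GenomicBin(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_probes=int(row["n_probes"]) if has_np else 1,
                    gc_fraction=float(row["gc"]) if has_gc else None,
                )
            )
        except DataError as exc:
            raise DataError(f"{path}, data row {i}: {exc}") from exc
    values = df[patient_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, c in enumerate(patient_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                i = int(col.isna().idxmax())
                raise DataError(
                    f"{path}: non-numeric value at data row {i}, column '{c}'"
                )
        values = values.astype(float)
    return ProfileMatrix(bins=bins, patients=patient_cols, values=values).sorted_by_position()


def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    cols: dict[str, object] = {
        "chrom": [b.chrom for b in pm.bins],
        "start": [b.start for b in pm.bins],
        "end": [b.end for b in pm.bins],
        "n_probes": [b.n_probes for b in pm.bins],
    }
    gc = pm.gc()
    if gc is not None:
        cols["gc"] = gc
    df = pd.DataFrame(cols)
    for j, p in enumerate(pm.patients):
        df[p] = pm.values[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def match_patients(tumor: ProfileMatrix, normal: ProfileMatrix) -> MatchedPair:
    """Restrict both matrices to shared patients, sorted lexicographically.

    The shared, deterministic patient order is what makes downstream GSVDs
    reproducible.  Idempotent.
    """
    shared = sorted(set(tumor.patients) & set(normal.patients))
    if len(shared) < 2:
        raise DataError(
            f"only {len(shared)} shared patient id(s); need at least 2 to match"
        )

    def restrict(pm: ProfileMatrix) -> ProfileMatrix:
        idx = [pm.patients.index(p) for p in shared]
        return ProfileMatrix(
            bins=list(pm.bins), patients=list(shared), values=pm.values[:, idx]
        )

    return MatchedPair(tumor=restrict(tumor), normal=restrict(normal))


# ---------------------------------------------------------------------------
# clinical tables

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_bool(raw: object, path: Path, row: int, col: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    try:  # pandas renders int columns with missing cells as floats ("1.0")
        f = float(s)
    except ValueError:
        f = None
    if f in (0.0, 1.0):
        return bool(f)
    raise DataError(f"{path}, data row {row}: {col} value {raw!r} not boolean")


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical outcome TSV into SurvivalRecords.

    Required columns: patient_id, os_months, os_event.  Optional: pfs_months,
    stage, platinum (missing cells stay missing).  A PFS exceeding OS is kept
    but flagged, with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "os_months", "os_event"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    records = []
    for i, row in df.iterrows():
        os_months = float(row["os_months"])
        rec = SurvivalRecord(
            patient_id=str(row["patient_id"]),
            os_months=os_months,
            os_event=_parse_bool(row["os_event"], path, int(i), "os_event"),
        )
        if "pfs_months" in df.columns and pd.notna(row["pfs_months"]):
            rec.pfs_months = float(row["pfs_months"])
            if rec.pfs_months > os_months:
                warnings.warn(
                    f"{path}, data row {i}: pfs_months > os_months; record flagged",
                    stacklevel=2,
                )
                rec.flagged = True
        if "stage" in df.columns and pd.notna(row["stage"]):
            rec.stage = _parse_stage(row["stage"])
        if "platinum" in df.columns and pd.notna(row["platinum"]):
            rec.platinum = _parse_bool(row["platinum"], path, int(i), "platinum")
        records.append(rec)
    return records


_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def _parse_stage(raw: object) -> int:
    s = str(raw).strip().lower()
    if s in _ROMAN:
        return _ROMAN[s]
    return int(float(s))


def write_clinical(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [int(r.os_event) for r in records],
            "pfs_months": [r.pfs_months for r in records],
            "stage": [r.stage for r in records],
            "platinum": [
                (int(r.platinum) if r.platinum is not None else None) for r in records
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# segments


def read_segments(bed_path: str | Path, arm_table_path: str | Path) -> SegmentSet:
    """Read segments from BED (chrom, start, end, name) plus a name->arm table."""
    bed_path, arm_table_path = Path(bed_path), Path(arm_table_path)
    arms = pd.read_csv(
        arm_table_path, sep="\t", header=None, names=["name", "arm"], dtype=str
    )
    arm_of = dict(zip(arms["name"], arms["arm"]))
    segs = []
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    for i, row in bed.iterrows():
        name = str(row["name"])
        if name not in arm_of:
            raise DataError(f"{bed_path}: segment {name!r} has no arm assignment")
        segs.append(
            Segment(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                label=name,
                arm=arm_of[name],
            )
        )
    return SegmentSet(segments=segs)


def write_segments(
    segments: SegmentSet, bed_path: str | Path, arm_table_path: str | Path
) -> None:
    with open(bed_path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\n")
    with open(arm_table_path, "w") as fh:
        for s in segments:
            fh.write(f"{s.label}\t{s.arm}\n")


# ---------------------------------------------------------------------------
# decomposition archives


def save_archive(factors: dict[str, np.ndarray], path: str | Path) -> None:
    """Save named factors to a single .npz archive."""
    np.savez(path, **{k: np.asarray(v) for k, v in factors.items()})


def load_archive(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as npz:
        return {k: npz[k] for k in npz.files}


def export_factors_tsv(factors: dict[str, np.ndarray], out_dir: str | Path) -> None:
    """Write one TSV per factor (vectors as single-column tables)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in factors.items():
        arr = np.asarray(arr)
        if arr.ndim <= 2:
            np.savetxt(out_dir / f"{name}.tsv", np.atleast_2d(arr.T).T, delimiter="\t")
        else:  # tensor: long-format (a, b, c, value) triplet table
            with open(out_dir / f"{name}.tsv", "w") as fh:
                fh.write("a\tb\tc\tvalue\n")
                for idx in np.ndindex(arr.shape):
                    fh.write(
                        "\t".join(str(i + 1) for i in idx) + f"\t{arr[idx]:.12g}\n"
                    )
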