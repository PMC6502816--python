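"""Data model and file I/O for quantification matrices, metadata and marker panels.

Matrices are protein x sample tables of log2-scale abundances with an explicit
missing-value mask (NaN).  All files are plain TSV / GMT text; empty cells mean
missing.  Alignment of the two fraction matrices uses canonical lexicographic
ordering so downstream outputs are deterministic across platforms.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRACTION_LYSATE = "lysate"
FRACTION_MITO = "mito"

#: Metadata columns, in file order.
METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "genotype",
    "condition",
    "cohort",
    "pair_id",
    "replicate",
]


class InputError(ValueError):
    """Raised when an input file or argument violates a documented contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise InputError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class QuantMatrix:
    """A protein x sample matrix of log2-scale abundances for one fraction.

    ``values`` is a float array with NaN marking missing entries.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    fraction: str = FRACTION_LYSATE

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.sample_ids, "sample")
        if np.isinf(self.values).any():
            raise InputError("matrix contains non-finite (inf) values")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.protein_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, fraction: str = FRACTION_LYSATE) -> "QuantMatrix":
        return cls(
            protein_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            fraction=fraction,
        )

    def subset(
        self,
        proteins: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "QuantMatrix":
        """Return a new matrix restricted (and reordered) to the given ids."""
        frame = self.to_frame()
        if proteins is not None:
            missing = [p for p in proteins if p not in frame.index]
            if missing:
                raise InputError(f"proteins not in matrix: {missing[:5]}")
            frame = frame.loc[list(proteins)]
        if samples is not None:
            missing = [s for s in samples if s not in frame.columns]
            if missing:
                raise InputError(f"samples not in matrix: {missing[:5]}")
            frame = frame[list(samples)]
        return QuantMatrix.from_frame(frame, fraction=self.fraction)

    def equals(self, other: "QuantMatrix") -> bool:
        return (
            self.protein_ids == other.protein_ids
            and self.sample_ids == other.sample_ids
            and self.fraction == other.fraction
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: subject, genotype, condition, cohort, pairing."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        self.table = self.table[METADATA_COLUMNS].copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        ids = list(self.table["sample_id"])
        _check_unique(ids, "sample")
        self.table["replicate"] = self.table["replicate"].fillna(0).astype(int)
        self.table["pair_id"] = self.table["pair_id"].where(
            self.table["pair_id"].notna() & (self.table["pair_id"].astype(str) != ""),
            other=pd.NA,
        )
        self._validate_pairs()
        self.table = self.table.set_index("sample_id", drop=False)

    def _validate_pairs(self) -> None:
        paired = self.table[self.table["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            if len(grp) != 2:
                raise InputError(
                    f"pair_id {pid!r} occurs {len(grp)} times; must occur exactly twice"
                )
            if grp["condition"].iloc[0] == grp["condition"].iloc[1]:
                raise InputError(
                    f"pair_id {pid!r}: both samples share condition "
                    f"{grp['condition'].iloc[0]!r}; pairs must contrast conditions"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "condition"])

    def group_labels(self, variables: Sequence[str] = ("condition", "genotype")) -> dict[str, str]:
        """Map sample_id -> composite group label joining the given variables with '-'."""
        out = {}
        for sid, row in self.table.iterrows():
            out[str(sid)] = "-".join(str(row[v]) for v in variables)
        return out

    def pairs(self) -> dict[str, tuple[str, str]]:
        """Map pair_id -> (case_sample, control_sample).

        Within a pair the sample whose condition sorts later lexicographically
        after case-normalization is not meaningful; the caller supplies which
        condition is the case via :meth:`pairs_oriented`.
        """
        out: dict[str, tuple[str, str]] = {}
        paired = self.table[self.table["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            a, b = grp["sample_id"].tolist()
            out[str(pid)] = (a, b)
        return out

    def pairs_oriented(self, case_condition: str) -> dict[str, tuple[str, str]]:
        """Map pair_id -> (case_sample, control_sample) using the case condition."""
        out: dict[str, tuple[str, str]] = {}
        paired = self.table[self.table["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            case = grp[grp["condition"] == case_condition]
            ctrl = grp[grp["condition"] != case_condition]
            if len(case) != 1 or len(ctrl) != 1:
                raise InputError(
                    f"pair_id {pid!r} has no sample with condition {case_condition!r}"
                )
            out[str(pid)] = (case["sample_id"].iloc[0], ctrl["sample_id"].iloc[0])
        return out

    def replicate_sample_ids(self) -> list[str]:
        return list(self.table.loc[self.table["replicate"] == 1, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in set(self.table["sample_id"])]
        if missing:
            raise InputError(f"samples not in metadata: {missing[:5]}")
        sub = self.table.loc[list(sample_ids)].reset_index(drop=True)
        return SampleMetadata(sub)


@dataclass
class MarkerPanel:
    """A named set of marker proteins for one organelle."""

    name: str
    organelle: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(str(m) for m in self.members)
        if not self.members:
            raise InputError(f"marker panel {self.name!r} is empty")


@dataclass
class AlignedPair:
    """Mito and lysate matrices restricted to shared proteins/samples.

    Both matrices carry identical protein and sample orderings (lexicographic).
    """

    mito: QuantMatrix
    lysate: QuantMatrix
    exclusive_to_mito: frozenset[str] = field(default_factory=frozenset)
    exclusive_to_lysate: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mito.protein_ids != self.lysate.protein_ids:
            raise InputError("aligned pair: protein orderings differ")
        if self.mito.sample_ids != self.lysate.sample_ids:
            raise InputError("aligned pair: sample orderings differ")
        shared = set(self.mito.protein_ids)
        if shared & set(self.exclusive_to_mito) or shared & set(self.exclusive_to_lysate):
            raise InputError("exclusive protein sets overlap the shared set")

    @property
    def n_shared_proteins(self) -> int:
        return len(self.mito.protein_ids)


# ---------------------------------------------------------------------------
# File I/O


def read_quant_matrix(path: str | Path, fraction: str = FRACTION_LYSATE) -> QuantMatrix:
    """Read a TSV matrix (first column = protein id, remaining columns = samples).

    Empty cells become missing values.  Duplicate protein or sample ids and
    non-numeric cells are rejected with the offending coordinates.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"{path}: empty file") from None
        if len(header) < 2:
            raise InputError(f"{path}: header has no sample columns")
        sample_ids = [h.strip() for h in header[1:]]
        _check_unique(sample_ids, f"sample (in {path.name})")
        protein_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise InputError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            protein_ids.append(row[0].strip())
            vals = []
            for colno, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell == "" or cell.upper() in {"NA", "NAN"}:
                    vals.append(math.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise InputError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, column {colno} "
                        f"(protein {row[0]!r}, sample {sample_ids[colno - 2]!r})"
                    ) from None
            rows.append(vals)
        _check_unique(protein_ids, f"protein (in {path.name})")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return QuantMatrix(protein_ids, sample_ids, values, fraction=fraction)


def write_quant_matrix(m: QuantMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with empty cells for missing values (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", *m.sample_ids])
        for pid, row in zip(m.protein_ids, m.values):
            writer.writerow([pid] + ["" if math.isnan(v) else repr(float(v)) for v in row])


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.replace({"": pd.NA})
    if "replicate" in frame.columns:
        frame["replicate"] = frame["replicate"].fillna("0").astype(int)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.reset_index(drop=True).copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_marker_panels_gmt(path: str | Path) -> list[MarkerPanel]:
    """Read marker panels from a GMT file (name TAB organelle TAB member...).

    Duplicate members within a line are dropped with a logged warning.
    """
    path = Path(path)
    panels: list[MarkerPanel] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, organelle, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if len(set(members)) != len(members):
                dupes = sorted({m for m in members if members.count(m) > 1})
                logger.warning(
                    "GMT %s line %d (%s): dropping duplicate members %s",
                    path.name, lineno, name, dupes,
                )
            panels.append(MarkerPanel(name=name, organelle=organelle, members=frozenset(members)))
    return panels


def write_marker_panels_gmt(panels: Iterable[MarkerPanel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in panels:
            fh.write("\t".join([p.name, p.organelle, *sorted(p.members)]) + "\n")


# ---------------------------------------------------------------------------
# Alignment and filtering


def align_fractions(
    mito: QuantMatrix, lysate: QuantMatrix, meta: SampleMetadata | None = None
) -> AlignedPair:
    """Restrict both fraction matrices to shared proteins and samples.

    Shared ids are put in canonical sorted order; proteins exclusive to one
    fraction are reported in the result.  Samples present in a matrix but
    absent from the metadata are an error.
    """
    mito_p, lys_p = set(mito.protein_ids), set(lysate.protein_ids)
    shared_p = sorted(mito_p & lys_p)
    shared_s = sorted(set(mito.sample_ids) & set(lysate.sample_ids))
    if not shared_p:
        raise InputError("no shared proteins between the two fractions")
    if not shared_s:
        raise InputError("no shared samples between the two fractions")
    if meta is not None:
        known = set(meta.sample_ids)
        for m in (mito, lysate):
            unknown = sorted(set(m.sample_ids) - known)
            if unknown:
                raise InputError(
                    f"samples in {m.fraction} matrix missing from metadata: {unknown[:5]}"
                )
    return AlignedPair(
        mito=mito.subset(shared_p, shared_s),
        lysate=lysate.subset(shared_p, shared_s),
        exclusive_to_mito=frozenset(mito_p - lys_p),
        exclusive_to_lysate=frozenset(lys_p - mito_p),
    )


def filter_by_presence(m: QuantMatrix, min_fraction_present: float) -> QuantMatrix:
    """Keep rows whose non-missing proportion is >= the threshold (order preserved)."""
    if not 0 < min_fraction_present <= 1:
        raise InputError(
            f"min_fraction_present must be in (0, 1], got {min_fraction_present}"
        )
    present = (~m.mask).mean(axis=1)
    keep = present >= min_fraction_present
    return QuantMatrix(
        [p for p, k in zip(m.protein_ids, keep) if k],
        m.sample_ids,
        m.values[keep],
        fraction=m.fraction,
    )


def log2_transform(m: QuantMatrix, pseudo_floor: float = 1.0) -> QuantMatrix:
    """Convert a linear-scale matrix to log2, flooring nonpositive values.

    Values <= 0 are replaced by ``pseudo_floor`` before the transform.
    """
    if pseudo_floor <= 0:
        raise InputError("pseudo_floor must be positive")
    vals = np.where(np.isnan(m.values), np.nan, np.maximum(m.values, pseudo_floor))
    return QuantMatrix(m.protein_ids, m.sample_ids, np.log2(vals), fraction=m.fraction)


def median_center(m: QuantMatrix) -> QuantMatrix:
    """Subtract each sample's median (per-sample centering within a fraction)."""
    med = np.nanmedian(m.values, axis=0, keepdims=True)
    return QuantMatrix(m.protein_ids, m.sample_ids, m.values - med, fraction=m.fraction)
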