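"""Fold-enrichment scores and technical-reproducibility QC.

The per-protein, per-sample enrichment score is the difference of log2
abundances between the organelle-enriched fraction and the total lysate.
Panel statistics average protein-first (mean over samples, then over panel
members) so proteins with more observations do not dominate a panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AlignedPair, InputError, MarkerPanel, QuantMatrix


@dataclass
class EnrichmentMatrix:
    """Per-protein per-sample log2 fold-enrichment scores (mito minus lysate)."""

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    n_exclusive_to_mito: int = 0
    n_exclusive_to_lysate: int = 0
    n_missing_entries: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise InputError("enrichment matrix shape mismatch")

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def as_quant_matrix(self) -> QuantMatrix:
        """View as a QuantMatrix (fraction label 'mtfe') for shared tooling."""
        return QuantMatrix(
            list(self.protein_ids), list(self.sample_ids), self.values.copy(), fraction="mtfe"
        )


@dataclass
class PanelStats:
    """Per-protein mean scores within one marker panel, plus the panel mean."""

    panel: str
    organelle: str
    per_protein_mean: pd.Series
    panel_mean: float
    members_absent: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    """Replicate CVs, panel statistics and cross-data-type sample correlations."""

    cv_percent: dict[str, pd.Series]
    panel_stats: list[PanelStats]
    spearman: pd.DataFrame | None = None

    def cv_median(self, data_type: str) -> float:
        return float(self.cv_percent[data_type].median())


def compute_mtfe(pair: AlignedPair) -> EnrichmentMatrix:
    """Score(p, s) = mito(p, s) - lysate(p, s); missing if either operand is."""
    values = pair.mito.values - pair.lysate.values
    return EnrichmentMatrix(
        protein_ids=list(pair.mito.protein_ids),
        sample_ids=list(pair.mito.sample_ids),
        values=values,
        n_exclusive_to_mito=len(pair.exclusive_to_mito),
        n_exclusive_to_lysate=len(pair.exclusive_to_lysate),
        n_missing_entries=int(np.isnan(values).sum()),
    )


def panel_stats(e: EnrichmentMatrix | QuantMatrix, panel: MarkerPanel) -> PanelStats:
    """Average a panel's member scores: per protein over samples, then over proteins."""
    frame = e.to_frame()
    present = sorted(panel.members & set(frame.index))
    if not present:
        raise InputError(f"no member of panel {panel.name!r} present in the matrix")
    absent = sorted(panel.members - set(frame.index))
    per_protein = frame.loc[present].mean(axis=1, skipna=True)
    return PanelStats(
        panel=panel.name,
        organelle=panel.organelle,
        per_protein_mean=per_protein,
        panel_mean=float(per_protein.mean(skipna=True)),
        members_absent=absent,
    )


def replicate_cv(
    m: QuantMatrix | EnrichmentMatrix,
    replicate_sample_ids: list[str],
) -> pd.Series:
    """Per-protein CV (%) over replicate samples, on linear-scale intensities.

    Values are 2**x for log2 matrices and enrichment scores alike; CV is
    100 * sample sd / mean.  Proteins observed in fewer than two replicates
    get NaN.
    """
    if len(replicate_sample_ids) < 2:
        raise InputError("need at least two replicate samples for CV")
    frame = m.to_frame()
    missing = [s for s in replicate_sample_ids if s not in frame.columns]
    if missing:
        raise InputError(f"replicate samples not in matrix: {missing}")
    linear = np.power(2.0, frame[list(replicate_sample_ids)])
    n = linear.notna().sum(axis=1)
    mean = linear.mean(axis=1, skipna=True)
    sd = linear.std(axis=1, ddof=1, skipna=True)
    cv = 100.0 * sd / mean
    cv[n < 2] = np.nan
    cv.name = "cv_percent"
    return cv


def cross_dataset_correlation(
    matrices: dict[str, QuantMatrix | EnrichmentMatrix],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Spearman correlations among all sample vectors of several data types.

    Columns are labeled ``<data type>:<sample id>``.  Correlations use
    pairwise-complete observations over the shared protein set; pairs with
    fewer than ``min_shared`` shared observations are reported missing.
    Ties get average ranks (pandas' default).
    """
    frames = {name: m.to_frame() for name, m in matrices.items()}
    shared = None
    for frame in frames.values():
        shared = set(frame.index) if shared is None else shared & set(frame.index)
    shared = sorted(shared or [])
    if len(shared) < min_shared:
        raise InputError(f"only {len(shared)} shared proteins; need >= {min_shared}")
    cols = {}
    for name, frame in frames.items():
        for s in frame.columns:
            cols[f"{name}:{s}"] = frame.loc[shared, s]
    combined = pd.DataFrame(cols)
    corr = combined.corr(method="spearman", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def qc_report(
    lysate: QuantMatrix,
    mito: QuantMatrix,
    mtfe: EnrichmentMatrix,
    panels: list[MarkerPanel],
    replicate_sample_ids: list[str] | None = None,
) -> QCReport:
    """Bundle replicate CVs, panel means and the cross-data-type correlogram."""
    cvs: dict[str, pd.Series] = {}
    if replicate_sample_ids:
        cvs = {
            "lysate": replicate_cv(lysate, replicate_sample_ids),
            "mito": replicate_cv(mito, replicate_sample_ids),
            "mtfe": replicate_cv(mtfe, replicate_sample_ids),
        }
    stats = []
    for panel in panels:
        try:
            stats.append(panel_stats(mtfe, panel))
        except InputError:
            continue
    corr = cross_dataset_correlation({"lysate": lysate, "mito": mito, "mtfe": mtfe})
    return QCReport(cv_percent=cvs, panel_stats=stats, spearman=corr)
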