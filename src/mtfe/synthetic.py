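"""Synthetic paired two-fraction cohorts with known ground truth.

The generator emulates processed protein-level quantification matrices from a
paired total-lysate / organelle-enriched experiment:

* log-normal baseline abundances (normal on the log2 scale);
* a per-organelle-class additive offset in the enriched fraction, so class
  marker panels recover a graded mean enrichment;
* ten condition-effect scenario types (no change, concordant changes,
  single-fraction changes, and moderate opposite-direction redistribution);
* a genotype confounder that shifts abundances in both fractions equally for
  most affected proteins (and therefore cancels in the enrichment score);
* a per-(protein, subject) biological component shared by the two fractions
  (it also cancels in the enrichment score) plus independent per-fraction
  measurement noise calibrated to realistic replicate CVs;
* optional technical replicate samples and completely-at-random missingness.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import (
    InputError,
    MarkerPanel,
    QuantMatrix,
    SampleMetadata,
    METADATA_COLUMNS,
)

#: default enriched-fraction offsets per organelle class (log2 units)
DEFAULT_CLASS_OFFSETS: dict[str, float] = {
    "mitochondrion": 1.62,
    "peroxisome": 0.82,
    "ER": 0.27,
    "cytosol": -1.03,
    "nucleus": -1.12,
    "spliceosome": -1.27,
}

#: default organelle class proportions (roughly liver-proteome-like)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "mitochondrion": 0.24,
    "peroxisome": 0.03,
    "ER": 0.10,
    "cytosol": 0.33,
    "nucleus": 0.20,
    "spliceosome": 0.10,
}


@dataclass(frozen=True)
class Scenario:
    """One condition-effect type: multipliers applied to the configured
    effect sizes in each fraction.

    ``moderate`` scenarios scale the per-fraction residual noise sd (the
    redistribution bound) instead of the main condition effect size.
    """

    id: int
    name: str
    lysate_mult: float
    mito_mult: float
    moderate: bool = False

    def effects(
        self, effect_size: float, lysate_sd: float, mito_sd: float, moderate_bound: float
    ) -> tuple[float, float]:
        """(lysate, mito) condition effects in log2 units."""
        if self.moderate:
            return (
                self.lysate_mult * moderate_bound * lysate_sd / 0.5,
                self.mito_mult * moderate_bound * mito_sd / 0.5,
            )
        return self.lysate_mult * effect_size, self.mito_mult * effect_size


def scenario_catalog() -> list[Scenario]:
    """The ten condition-effect scenario types.

    The taxonomy covers: no change (1); concordant abundance change in both
    fractions, up and down (2, 7) leaving the enrichment score unchanged;
    change in one fraction only, each direction (3, 4, 8, 9); a large
    opposite-direction change (5); and moderate opposite-direction
    redistribution in either direction (6, 10), whose lysate change stays at
    or below the configured moderate bound (default one residual noise sd) so
    whole-lysate tests are underpowered while the enrichment score shifts.
    The numbering is this package's own; it is a taxonomy, not a claim about
    any external figure's panel order.
    """
    return [
        Scenario(1, "null", 0.0, 0.0),
        Scenario(2, "concordant_up", 1.0, 1.0),
        Scenario(3, "mito_only_up", 0.0, 1.0),
        Scenario(4, "lysate_only_up", 1.0, 0.0),
        Scenario(5, "strong_opposite_to_mito", -1.0, 1.0),
        Scenario(6, "redistribution_to_mito", -0.5, 0.5, moderate=True),
        Scenario(7, "concordant_down", -1.0, -1.0),
        Scenario(8, "mito_only_down", 0.0, -1.0),
        Scenario(9, "lysate_only_down", -1.0, 0.0),
        Scenario(10, "redistribution_to_cytosol", 0.5, -0.5, moderate=True),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.  Defaults give a discovery-style
    cohort: four condition x genotype groups (8/6/8/6), ~2500 proteins, a
    graded organelle offset, and noise calibrated so replicate CVs have
    medians near 6% (enriched fraction) and 10% (lysate)."""

    n_proteins: int = 2500
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    class_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_OFFSETS)
    )
    baseline_mean: float = 14.0
    baseline_sd: float = 2.0
    # condition effects; None -> ~1% of proteins per non-null scenario
    scenario_counts: dict[int, int] | None = None
    condition_effect_size: float = 1.0
    moderate_bound: float = 1.0  # in units of the per-fraction residual sd
    # genotype confounder
    genotype_effect_size: float = 0.8
    genotype_fraction: float = 0.25
    genotype_unequal_fraction: float = 0.05  # minority of affected proteins: mito only
    # noise
    biological_sd: float = 0.35  # per (protein, subject), shared by both fractions
    lysate_noise_sd: float = 0.165  # residual, per fraction; calibrated so the
    mito_noise_sd: float = 0.0945  # 5-replicate CV medians land near 10.4% / 6%
    # design
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "Ctrl-WT": 8,
            "Ctrl-KO": 6,
            "DEN-WT": 8,
            "DEN-KO": 6,
        }
    )
    paired: bool = False
    n_pairs: int = 5
    conditions: tuple[str, str] = ("Ctrl", "DEN")
    paired_conditions: tuple[str, str] = ("Adjacent", "Tumor")
    n_replicates: int = 0
    missing_rate: float = 0.0
    cohort: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise InputError("n_proteins must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"class proportions must sum to 1, got {total}")
        for k, v in self.class_proportions.items():
            if v < 0:
                raise InputError(f"negative proportion for class {k!r}")
            if k not in self.class_offsets:
                raise InputError(f"class {k!r} has no configured offset")
        for sd in (self.baseline_sd, self.biological_sd, self.lysate_noise_sd, self.mito_noise_sd):
            if sd < 0:
                raise InputError("standard deviations must be >= 0")
        counts = self.resolved_scenario_counts()
        n_effect = sum(counts.values())
        if n_effect > self.n_proteins:
            raise InputError(
                f"scenario counts ({n_effect}) exceed protein count ({self.n_proteins})"
            )
        known = {s.id for s in scenario_catalog()}
        unknown = set(counts) - known
        if unknown:
            raise InputError(f"unknown scenario ids: {sorted(unknown)}")
        if not self.paired:
            for g, n in self.group_sizes.items():
                if n < 2:
                    raise InputError(f"group {g!r} smaller than 2")
        elif self.n_pairs < 2:
            raise InputError("need at least 2 pairs")
        if not 0 <= self.missing_rate < 1:
            raise InputError("missing_rate must be in [0, 1)")
        if not 0 <= self.genotype_fraction <= 1:
            raise InputError("genotype_fraction must be in [0, 1]")

    def resolved_scenario_counts(self) -> dict[int, int]:
        if self.scenario_counts is not None:
            return self.scenario_counts
        per = max(1, round(0.01 * self.n_proteins))
        return {i: per for i in range(2, 11)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("scenario_counts",):
            if key in d and d[key] is not None:
                d[key] = {int(k): int(v) for k, v in d[key].items()}
        for key in ("conditions", "paired_conditions"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth per protein: organelle class, scenario and effect sizes."""

    table: pd.DataFrame
    config: SimulationConfig

    def proteins_of_scenario(self, scenario_id: int) -> list[str]:
        return sorted(self.table.index[self.table["scenario"] == scenario_id])

    def marker_panels(self) -> list[MarkerPanel]:
        panels = []
        for cls_name, grp in self.table.groupby("organelle"):
            panels.append(
                MarkerPanel(
                    name=f"{cls_name}_markers",
                    organelle=str(cls_name),
                    members=frozenset(grp.index),
                )
            )
        return sorted(panels, key=lambda p: p.name)


def _build_metadata(cfg: SimulationConfig) -> SampleMetadata:
    rows = []
    if cfg.paired:
        adj, tum = cfg.paired_conditions
        for i in range(cfg.n_pairs):
            subj = f"M{i + 1:02d}"
            for cond in (tum, adj):
                rows.append(
                    {
                        "sample_id": f"{subj}_{cond}",
                        "subject_id": subj,
                        "genotype": "WT",
                        "condition": cond,
                        "cohort": cfg.cohort,
                        "pair_id": f"P{i + 1:02d}",
                        "replicate": 0,
                    }
                )
    else:
        counter = 0
        for group, size in cfg.group_sizes.items():
            cond, geno = group.split("-", 1)
            for _ in range(size):
                counter += 1
                subj = f"M{counter:02d}"
                rows.append(
                    {
                        "sample_id": f"{subj}_{group}",
                        "subject_id": subj,
                        "genotype": geno,
                        "condition": cond,
                        "cohort": cfg.cohort,
                        "pair_id": None,
                        "replicate": 0,
                    }
                )
    for r in range(cfg.n_replicates):
        rows.append(
            {
                "sample_id": f"REP{r + 1:02d}",
                "subject_id": "REPLICATE",
                "genotype": "WT",
                "condition": "Replicate",
                "cohort": cfg.cohort,
                "pair_id": None,
                "replicate": 1,
            }
        )
    frame = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return SampleMetadata(frame)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[QuantMatrix, QuantMatrix, SampleMetadata, SimulationTruth]:
    """Generate (mito, lysate, metadata, truth) for one synthetic cohort.

    Model per protein p and sample s (all additive on the log2 scale):

        lysate(p,s) = baseline(p) + genotype(p)*[KO] + lys_effect(p)*[case]
                      + bio(p, subject(s)) + eps_l(p,s)
        mito(p,s)   = baseline(p) + offset(class(p)) + genotype(p)*[KO]
                      + mito_effect(p)*[case] + bio(p, subject(s)) + eps_m(p,s)

    so the enrichment score is offset + (mito-lysate effect difference) plus
    independent per-fraction noise: both the genotype confounder (for the
    equal-fraction majority) and the shared biological component cancel.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    catalog = {s.id: s for s in scenario_catalog()}

    P = cfg.n_proteins
    protein_ids = [f"PROT{i + 1:05d}" for i in range(P)]

    # organelle classes: deterministic counts from proportions, then shuffled
    classes = sorted(cfg.class_proportions)
    counts = {c: int(round(cfg.class_proportions[c] * P)) for c in classes}
    drift = P - sum(counts.values())
    counts[classes[0]] += drift
    class_arr = np.repeat(classes, [counts[c] for c in classes])
    rng.shuffle(class_arr)
    offsets = np.array([cfg.class_offsets[c] for c in class_arr])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=P)

    # scenario assignment
    scenario = np.ones(P, dtype=int)
    perm = rng.permutation(P)
    pos = 0
    scenario_counts = cfg.resolved_scenario_counts()
    for sid in sorted(scenario_counts):
        cnt = scenario_counts[sid]
        scenario[perm[pos : pos + cnt]] = sid
        pos += cnt
    lys_eff = np.zeros(P)
    mito_eff = np.zeros(P)
    for sid, scen in catalog.items():
        sel = scenario == sid
        le, me = scen.effects(
            cfg.condition_effect_size,
            cfg.lysate_noise_sd,
            cfg.mito_noise_sd,
            cfg.moderate_bound,
        )
        lys_eff[sel] = le
        mito_eff[sel] = me

    # genotype confounder
    geno_eff = np.zeros(P)
    affected = rng.random(P) < cfg.genotype_fraction
    signs = rng.choice([-1.0, 1.0], size=P)
    geno_eff[affected] = signs[affected] * cfg.genotype_effect_size
    unequal = affected & (rng.random(P) < cfg.genotype_unequal_fraction)

    meta = _build_metadata(cfg)
    samples = meta.sample_ids
    S = len(samples)
    subjects = sorted(set(meta.table["subject_id"]))
    subj_index = {s: i for i, s in enumerate(subjects)}
    bio = rng.normal(0.0, cfg.biological_sd, size=(P, len(subjects)))

    case_cond = cfg.paired_conditions[1] if cfg.paired else cfg.conditions[1]
    is_case = np.array(
        [meta.table.loc[s, "condition"] == case_cond for s in samples], dtype=float
    )
    is_ko = np.array([meta.table.loc[s, "genotype"] == "KO" for s in samples], dtype=float)
    bio_cols = np.array([subj_index[meta.table.loc[s, "subject_id"]] for s in samples])

    systematic_l = (
        baseline[:, None]
        + geno_eff[:, None] * is_ko[None, :]
        + lys_eff[:, None] * is_case[None, :]
        + bio[:, bio_cols]
    )
    # for the unequal minority the genotype effect hits only the enriched fraction
    geno_l = np.where(unequal, 0.0, geno_eff)
    systematic_l += (geno_l - geno_eff)[:, None] * is_ko[None, :]
    systematic_m = (
        baseline[:, None]
        + offsets[:, None]
        + geno_eff[:, None] * is_ko[None, :]
        + mito_eff[:, None] * is_case[None, :]
        + bio[:, bio_cols]
    )
    eps_l = rng.normal(0.0, cfg.lysate_noise_sd, size=(P, S))
    eps_m = rng.normal(0.0, cfg.mito_noise_sd, size=(P, S))
    L = systematic_l + eps_l
    M = systematic_m + eps_m

    if cfg.missing_rate > 0:
        L[rng.random((P, S)) < cfg.missing_rate] = np.nan
        M[rng.random((P, S)) < cfg.missing_rate] = np.nan

    lysate = QuantMatrix(protein_ids, samples, L, fraction="lysate")
    mito = QuantMatrix(protein_ids, samples, M, fraction="mito")
    truth = SimulationTruth(
        table=pd.DataFrame(
            {
                "organelle": class_arr,
                "scenario": scenario,
                "lysate_effect": lys_eff,
                "mito_effect": mito_eff,
                "mtfe_effect": mito_eff - lys_eff,
                "genotype_effect": geno_eff,
                "genotype_unequal": unequal,
                "baseline": baseline,
            },
            index=pd.Index(protein_ids, name="protein_id"),
        ),
        config=cfg,
    )
    return mito, lysate, meta, truth


def evaluate_recovery(
    truth: SimulationTruth,
    tables: Mapping[str, "object"],
    alpha: float = 0.05,
    criterion: str = "raw",
) -> pd.DataFrame:
    """Per-scenario detection rates and type-I error per data type.

    ``tables`` maps data-type name -> DifferentialTable computed on the
    generated cohort.  ``criterion`` selects what counts as detected:
    'raw' (ANOVA p < alpha), 'adjusted' (BH-adjusted ANOVA p < alpha) or
    'flag' (significant in any pairwise comparison, i.e. adjusted ANOVA and
    Tukey both below alpha).
    """
    if criterion not in {"raw", "adjusted", "flag"}:
        raise InputError(f"unknown criterion {criterion!r}")
    rows = []
    names = {s.id: s.name for s in scenario_catalog()}
    for dtype, table in tables.items():
        tab = table.table
        if set(tab.index) != set(truth.table.index):
            raise InputError(f"{dtype}: protein universe differs from truth")
        if criterion == "raw":
            detected = tab["p"] < alpha
        elif criterion == "adjusted":
            detected = tab["p_adj"] < alpha
        else:
            sig = set(table.significant_union())
            detected = pd.Series(tab.index.isin(sig), index=tab.index)
        detected = detected.fillna(False)
        for sid, grp in truth.table.groupby("scenario"):
            hits = detected.reindex(grp.index).fillna(False)
            rows.append(
                {
                    "data_type": dtype,
                    "scenario": int(sid),
                    "scenario_name": names[int(sid)],
                    "n_proteins": len(grp),
                    "rate": float(hits.mean()),
                    "is_null": int(sid) == 1,
                }
            )
    out = pd.DataFrame(rows)
    out["kind"] = np.where(out["is_null"], "type_i_error", "detection_rate")
    return out.drop(columns="is_null")
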