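"""Synthetic paired cell-screen / patient-cohort generator.

The generator plants the statistical structure that makes translational
drug-response modeling hard and its diagnostics meaningful:

* a shared gene universe with a configurable fraction of duplicated gene
  names (different probes reporting under one symbol);
* a global train-vs-patient distribution shift: every gene receives an
  additive and a multiplicative batch offset on the patient side;
* signal genes whose expression drives a latent drug sensitivity through
  fixed weights; housekeeping genes with zero weight that carry only the
  batch variation (usable as negative controls);
* a designated landmark subset containing a configurable share of the
  signal genes;
* a multi-drug response table in which each drug mixes a general
  sensitivity factor (weight ``shared_fraction``) with a drug-specific
  factor, so cross-drug response correlation is tunable from 0 to 1;
* small patient cohorts with a roughly balanced responder split, the
  responder being the patient whose latent sensitivity exceeds the
  (1 - responder_fraction) cohort quantile.

Every draw is reproducible from the seed, and the returned
:class:`GroundTruth` suffices to recompute the noiseless responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CellScreen, DataError, ExpressionMatrix, PatientCohort

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_paired_datasets",
    "generate_multi_drug_screen",
    "expected_cross_drug_correlation",
    "oracle_scores",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic translational setting.

    Defaults mirror a small translational scenario: a few-hundred-sample
    cell screen, a 24-patient cohort with a balanced responder split, a
    clear train-vs-patient expression shift, and moderate per-gene signal.
    """

    n_genes: int = 1000
    n_signal_genes: int = 40
    n_housekeeping: int = 100
    n_landmark: int = 80
    landmark_signal_fraction: float = 0.5
    n_cell_lines: int = 150
    n_patients: int = 24
    effect_size: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    noise_sd: float = 1.0
    n_drugs: int = 1
    shared_fraction: float = 0.5
    responder_fraction: float = 0.5
    duplicate_gene_fraction: float = 0.05
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes + self.n_housekeeping > self.n_genes:
            raise DataError("signal + housekeeping genes exceed the gene budget")
        if self.n_landmark > self.n_genes:
            raise DataError("landmark set exceeds the gene budget")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if not 0 <= self.shared_fraction <= 1:
            raise DataError("shared_fraction must be in [0, 1]")
        if not 0 < self.responder_fraction < 1:
            raise DataError("responder_fraction must be in (0, 1)")
        if not 0 <= self.duplicate_gene_fraction < 1:
            raise DataError("duplicate_gene_fraction must be in [0, 1)")
        if self.n_drugs < 1:
            raise DataError("need at least one drug")

    @classmethod
    def scaled(cls, n_genes: int, **overrides) -> "SimulationParams":
        """Params with gene-role sizes proportional to the gene budget.

        Signal genes ~10%, housekeeping ~20%, landmark ~15% of the universe
        (roughly the proportions of the default parameter set).
        """
        sizes = {
            "n_signal_genes": max(5, n_genes // 10),
            "n_housekeeping": max(10, n_genes // 5),
            "n_landmark": max(8, int(n_genes * 0.15)),
        }
        sizes.update(overrides)
        return cls(n_genes=n_genes, **sizes)


@dataclass
class GroundTruth:
    """Everything needed to recompute the noiseless planted responses."""

    signal_gene_ids: list[str]
    shared_weights: pd.Series  # per signal gene
    drug_weights: pd.DataFrame  # drug x signal gene (drug-specific factors)
    drug_intercepts: pd.Series
    latent_cell_sensitivity: pd.DataFrame  # drug x cell line, noiseless mix
    latent_patient_sensitivity: pd.Series  # administered drug, per patient
    batch_shift: pd.Series  # per gene additive offset on the patient side
    batch_scale: pd.Series  # per gene multiplicative factor on the patient side
    responder_threshold: float
    administered_drug: str
    mixed_weights: pd.Series = None  # administered drug's effective weights


def _drug_names(n: int) -> list[str]:
    return [f"drug_{i:03d}" for i in range(n)]


def _latent(weights: pd.Series, expression: pd.DataFrame, baseline: pd.Series) -> pd.Series:
    """Latent sensitivity of each sample: sum over signal genes of w_g * (x_g - mu_g)."""
    sub = expression.loc[weights.index]
    centered = sub.sub(baseline.loc[weights.index], axis=0)
    return centered.mul(weights, axis=0).sum(axis=0)


def generate_paired_datasets(
    params: SimulationParams,
) -> tuple[CellScreen, PatientCohort, GroundTruth]:
    """Draw one paired (cell screen, patient cohort) dataset.

    Cell-line expression is Gaussian per gene around a gene-specific
    baseline; the latent sensitivity of a sample is a weighted sum of its
    signal-gene expression.  Per drug, ln(IC50) = intercept - mixed latent
    + noise (lower response = more sensitive, so higher latent sensitivity
    lowers ln(IC50)).  Patient expression adds per-gene additive and
    multiplicative batch offsets on top of the same clean model, and the
    patient responder label thresholds the clean latent sensitivity of the
    administered drug (the first drug) at the (1 - responder_fraction)
    quantile.
    """
    rng = np.random.default_rng(params.seed)
    g, ncl, npat = params.n_genes, params.n_cell_lines, params.n_patients

    base_ids = [f"gene_{i:05d}" for i in range(g)]
    baseline = pd.Series(
        rng.normal(params.baseline_mean, params.baseline_sd, g), index=base_ids
    )

    # Gene roles: signal first, then housekeeping, then filler.
    signal_ids = base_ids[: params.n_signal_genes]
    housekeeping_ids = base_ids[
        params.n_signal_genes: params.n_signal_genes + params.n_housekeeping
    ]
    filler_ids = base_ids[params.n_signal_genes + params.n_housekeeping:]

    # Landmark set: a configurable share of signal genes plus filler.
    n_lm_signal = min(
        int(round(params.landmark_signal_fraction * params.n_landmark)),
        len(signal_ids),
    )
    n_lm_filler = params.n_landmark - n_lm_signal
    if n_lm_filler > len(filler_ids):
        raise DataError("landmark set cannot be filled from non-signal genes")
    landmark_ids = list(signal_ids[:n_lm_signal]) + list(filler_ids[:n_lm_filler])

    # Signal weights: shared factor and per-drug specific factors, scaled so
    # the latent variance is ~effect_size^2 regardless of the gene count.
    scale = params.effect_size / np.sqrt(max(params.n_signal_genes, 1))
    shared_w = pd.Series(rng.normal(0.0, 1.0, len(signal_ids)) * scale, index=signal_ids)
    drugs = _drug_names(params.n_drugs)
    drug_w = pd.DataFrame(
        rng.normal(0.0, 1.0, (params.n_drugs, len(signal_ids))) * scale,
        index=drugs,
        columns=signal_ids,
    )

    cell_ids = [f"cell_{i:04d}" for i in range(ncl)]
    patient_ids = [f"patient_{i:04d}" for i in range(npat)]
    cell_expr = pd.DataFrame(
        baseline.to_numpy()[:, None] + rng.normal(0.0, 1.0, (g, ncl)),
        index=base_ids,
        columns=cell_ids,
    )
    patient_clean = pd.DataFrame(
        baseline.to_numpy()[:, None] + rng.normal(0.0, 1.0, (g, npat)),
        index=base_ids,
        columns=patient_ids,
    )

    # Per-drug response: intercept - mixed latent + noise.
    sf = params.shared_fraction
    shared_latent_cells = _latent(shared_w, cell_expr, baseline)
    intercepts = pd.Series(rng.normal(2.0, 0.5, params.n_drugs), index=drugs)
    latent_rows = {}
    response_rows = {}
    for d in drugs:
        specific = _latent(drug_w.loc[d], cell_expr, baseline)
        mixed = sf * shared_latent_cells + (1.0 - sf) * specific
        latent_rows[d] = mixed
        response_rows[d] = (
            intercepts[d] - mixed + rng.normal(0.0, params.noise_sd, ncl)
        )
    latent_cells = pd.DataFrame(latent_rows).T
    response = pd.DataFrame(response_rows).T
    response.columns = cell_ids

    # Patient latent sensitivity of the administered (first) drug, computed
    # on the clean (pre-batch) expression.
    administered = drugs[0]
    shared_latent_pat = _latent(shared_w, patient_clean, baseline)
    specific_pat = _latent(drug_w.loc[administered], patient_clean, baseline)
    latent_pat = sf * shared_latent_pat + (1.0 - sf) * specific_pat
    if float(latent_pat.std()) > 0:
        threshold = float(latent_pat.quantile(1.0 - params.responder_fraction))
        labels = (latent_pat > threshold).astype(int)
        if labels.nunique() < 2:  # quantile tie swallowed a class
            labels.loc[latent_pat.idxmax()] = 1
    else:
        # degenerate latent (e.g. zero effect size): the responder label is
        # a balanced random draw, independent of expression by construction
        threshold = 0.0
        n_resp = max(1, int(round(params.responder_fraction * npat)))
        chosen = rng.choice(npat, size=min(n_resp, npat - 1), replace=False)
        labels = pd.Series(0, index=patient_ids, dtype=int)
        labels.iloc[chosen] = 1

    # Train-vs-patient batch: per-gene additive + multiplicative offsets
    # applied to the centered patient values (housekeeping genes included).
    shift = pd.Series(rng.normal(0.0, params.batch_shift_sd, g), index=base_ids)
    gain = pd.Series(
        np.abs(1.0 + rng.normal(0.0, params.batch_scale_sd, g)), index=base_ids
    )
    patient_expr = (
        patient_clean.sub(baseline, axis=0)
        .mul(gain, axis=0)
        .add(baseline + shift, axis=0)
    )

    # Duplicate a fraction of filler gene ids: append an extra row per
    # duplicated id (an independent noisy re-measurement) on both sides.
    n_dup = int(round(params.duplicate_gene_fraction * g))
    dup_pool = filler_ids[n_lm_filler:]
    n_dup = min(n_dup, len(dup_pool))
    if n_dup:
        dup_ids = list(rng.choice(dup_pool, size=n_dup, replace=False))
        extra_cell = pd.DataFrame(
            baseline.loc[dup_ids].to_numpy()[:, None]
            + rng.normal(0.0, 1.0, (n_dup, ncl)),
            index=dup_ids,
            columns=cell_ids,
        )
        extra_pat = pd.DataFrame(
            baseline.loc[dup_ids].to_numpy()[:, None]
            + shift.loc[dup_ids].to_numpy()[:, None]
            + rng.normal(0.0, 1.0, (n_dup, npat)),
            index=dup_ids,
            columns=patient_ids,
        )
        cell_expr = pd.concat([cell_expr, extra_cell])
        patient_expr = pd.concat([patient_expr, extra_pat])

    tissues = pd.Series(
        rng.choice(["breast", "lung", "ovary", "blood", "skin"], size=ncl),
        index=cell_ids,
    )
    screen = CellScreen(
        expression=ExpressionMatrix(cell_expr),
        response=response,
        tissues=tissues,
        landmark_genes=frozenset(landmark_ids),
        housekeeping_genes=frozenset(housekeeping_ids),
    )
    cohort = PatientCohort(expression=ExpressionMatrix(patient_expr), response=labels)
    truth = GroundTruth(
        signal_gene_ids=list(signal_ids),
        shared_weights=shared_w,
        drug_weights=drug_w,
        drug_intercepts=intercepts,
        latent_cell_sensitivity=latent_cells,
        latent_patient_sensitivity=latent_pat,
        batch_shift=shift,
        batch_scale=gain,
        responder_threshold=threshold,
        administered_drug=administered,
        mixed_weights=sf * shared_w + (1.0 - sf) * drug_w.loc[administered],
    )
    return screen, cohort, truth


def generate_multi_drug_screen(params: SimulationParams) -> CellScreen:
    """Convenience wrapper producing a screen with >= 2 drugs.

    All drugs share the general sensitivity factor with weight
    ``shared_fraction``; pairwise correlation of the noiseless responses
    rises monotonically with it (1 = all drugs rank-identical, 0 =
    independent drug-specific factors).
    """
    if params.n_drugs < 2:
        raise DataError("generate_multi_drug_screen needs n_drugs >= 2")
    screen, _, _ = generate_paired_datasets(params)
    return screen


def expected_cross_drug_correlation(shared_fraction: float) -> float:
    """Closed-form expected correlation of two noiseless drug responses.

    With latent mix s_mix = f*s + (1-f)*s_d, independent standardized
    shared and specific factors of equal variance, the covariance of two
    drugs is f^2 var(s) and each variance is f^2 var(s) + (1-f)^2 var(s_d),
    so corr = f^2 / (f^2 + (1-f)^2).
    """
    f = float(shared_fraction)
    denom = f**2 + (1.0 - f) ** 2
    return f**2 / denom if denom > 0 else 0.0


def oracle_scores(truth: GroundTruth, expression: ExpressionMatrix) -> pd.Series:
    """Sensitivity scores from the true planted weights (higher = responder).

    Applies the administered drug's mixed weight vector to any expression
    matrix containing the signal genes; used for parameter-recovery checks.
    """
    values = expression.values
    missing = [gid for gid in truth.signal_gene_ids if gid not in values.index]
    if missing:
        raise DataError(f"expression lacks signal genes: {missing[:5]}")
    mixed = truth.mixed_weights
    sub = values.loc[mixed.index]
    return sub.mul(mixed, axis=0).sum(axis=0)
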