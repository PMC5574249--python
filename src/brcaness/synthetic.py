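"""Synthetic discovery cohorts and trial tables.

The discovery generator emulates a two-assay setting: a latent expression
phenotype drives mean shifts in a set of informative genes, while the
recorded reference label (the copy-number call) disagrees with that
phenotype with class-specific discordance probabilities. Sensitivity and
specificity of a perfect expression classifier against the reference label
are therefore 1 - discordance_pos and 1 - discordance_neg by construction
(defaults 0.97 / 0.73). The matrix is emitted as background-subtracted
linear-scale intensities so the full preprocessing chain applies.

The trial generator draws a two-arm cohort with fixed arm sizes, a Bernoulli
biomarker class, hormone-receptor status conditional on the biomarker
(strongly confounded, as in the real cohort), a tumor-size category with a
small missingness rate, and a binary pCR outcome with per-(arm, biomarker)
response probabilities. Default response probabilities give generating
per-arm odds ratios of ~3.17 (experimental) and ~0.39 (control).

One global seed drives a named sub-stream per generator, so adding a
generator never perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, LabeledCohort, ValidationError

__all__ = [
    "DiscoverySimConfig",
    "TrialSimConfig",
    "simulate_discovery",
    "simulate_trial",
    "null_pcr_prob",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, named sub-stream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def _check_positive(value: float, name: str) -> None:
    if value <= 0:
        raise ValidationError(f"{name} must be positive, got {value}")


@dataclass
class DiscoverySimConfig:
    """Study conditions for a synthetic discovery cohort.

    ``discordance_pos`` / ``discordance_neg`` are the probabilities that the
    expression phenotype disagrees with the recorded reference label for
    label-positive / label-negative samples; they set the ceiling on the
    sensitivity / specificity achievable against that label (0.97 / 0.73 at
    the defaults). ``effect_cv`` is the coefficient of variation of the
    per-gene effect magnitudes (gamma-distributed, mean 1) and ``frac_up``
    the fraction of informative genes up-regulated in the positive
    phenotype. Mixed directions (the default) are essential: a Pearson
    correlation with a centroid is invariant to adding a constant to that
    centroid, so a signature whose genes all shift the same way by similar
    amounts carries almost no correlation-difference signal.
    ``baseline_mean`` / ``baseline_sd`` are the per-gene log2-intensity
    baselines.
    """

    n_samples: int = 128
    n_genes: int = 2000
    n_informative: int = 150
    label_prevalence: float = 0.48
    effect_size: float = 1.0
    noise_sd: float = 1.0
    discordance_pos: float = 0.03
    discordance_neg: float = 0.27
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    effect_cv: float = 0.25
    frac_up: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_informative", "n_batches"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v}")
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative must not exceed n_genes")
        if not (0.0 < self.label_prevalence < 1.0):
            raise ValidationError("label_prevalence must lie in (0, 1)")
        for name in ("discordance_pos", "discordance_neg", "missing_rate", "frac_up"):
            _check_prob(getattr(self, name), name)
        _check_positive(self.noise_sd, "noise_sd")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        for name in ("batch_shift_sd", "baseline_sd", "effect_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of a simulated discovery cohort."""

    latent: pd.Series
    informative_genes: list
    effects: pd.Series


def simulate_discovery(
    config: DiscoverySimConfig, return_truth: bool = False
) -> LabeledCohort | tuple[LabeledCohort, SimTruth]:
    """Draw a labeled discovery cohort.

    The expression values are background-subtracted linear-scale intensities
    (2**log2signal - 10), with MCAR missingness at ``missing_rate``; the
    reference label is the copy-number-style call, discordant with the latent
    expression phenotype at the configured rates.
    """
    cfg = config
    rng = _rng(cfg.seed, "discovery")

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]

    label = (rng.random(cfg.n_samples) < cfg.label_prevalence).astype(int)
    # guarantee both classes (tiny cohorts in tests)
    if label.sum() == 0:
        label[0] = 1
    if label.sum() == cfg.n_samples:
        label[0] = 0
    flip_p = np.where(label == 1, cfg.discordance_pos, cfg.discordance_neg)
    flips = rng.random(cfg.n_samples) < flip_p
    latent = np.where(flips, 1 - label, label)

    informative = rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)
    informative.sort()
    effects = np.zeros(cfg.n_genes)
    if cfg.effect_cv > 0:
        shape = 1.0 / cfg.effect_cv**2
        h = rng.gamma(shape, scale=1.0 / shape, size=cfg.n_informative)
    else:
        h = np.ones(cfg.n_informative)
    signs = np.where(rng.random(cfg.n_informative) < cfg.frac_up, 1.0, -1.0)
    effects[informative] = cfg.effect_size * cfg.noise_sd * h * signs

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    batch = np.tile(np.arange(cfg.n_batches), cfg.n_samples // cfg.n_batches + 1)[
        : cfg.n_samples
    ]
    batch = rng.permutation(batch)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_batches))

    log_signal = (
        baseline[:, None]
        + effects[:, None] * latent[None, :]
        + batch_shift[:, batch]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    )
    raw = np.exp2(log_signal) - 10.0
    if cfg.missing_rate > 0:
        holes = rng.random(raw.shape) < cfg.missing_rate
        # never blank out an entire gene row
        full_rows = holes.all(axis=1)
        holes[full_rows, 0] = False
        raw = np.where(holes, np.nan, raw)

    values = pd.DataFrame(raw, index=gene_ids, columns=sample_ids)
    batch_series = pd.Series([f"B{b}" for b in batch], index=sample_ids, name="batch")
    cohort = LabeledCohort(
        expr=ExpressionMatrix(values=values, batch=batch_series),
        label=pd.Series(label, index=sample_ids, name="label"),
    )
    if not return_truth:
        return cohort
    truth = SimTruth(
        latent=pd.Series(latent, index=sample_ids, name="latent"),
        informative_genes=[gene_ids[i] for i in informative],
        effects=pd.Series(effects, index=gene_ids, name="effect"),
    )
    return cohort, truth


def _default_pcr_prob() -> dict:
    # generating odds ratios: experimental (0.50/0.24) -> 3.17,
    # control (0.12/0.26) -> 0.388
    return {
        ("experimental", "positive"): 0.50,
        ("experimental", "negative"): 0.24,
        ("control", "positive"): 0.12,
        ("control", "negative"): 0.26,
    }


def null_pcr_prob(odds_ratio: float = 2.0, p_ctrl_neg: float = 0.20, p_exp_neg: float = 0.30) -> dict:
    """Response probabilities with an identical biomarker odds ratio in both
    arms (exact null for the biomarker x treatment interaction)."""

    def _shift(p: float) -> float:
        odds = p / (1 - p) * odds_ratio
        return odds / (1 + odds)

    return {
        ("control", "negative"): p_ctrl_neg,
        ("control", "positive"): _shift(p_ctrl_neg),
        ("experimental", "negative"): p_exp_neg,
        ("experimental", "positive"): _shift(p_exp_neg),
    }


@dataclass
class TrialSimConfig:
    """Study conditions for a synthetic two-arm trial table.

    Defaults emulate the real cohort: 72 experimental vs 44 control
    patients, ~47% biomarker-positive, strong biomarker-HR confounding
    (14.5% HR+ among positives, 78.7% among negatives), and per-arm
    biomarker-response odds ratios of ~3.17 / ~0.39.
    """

    n_experimental: int = 72
    n_control: int = 44
    p_biomarker_pos: float = 55 / 116
    p_hrpos_given_pos: float = 0.145
    p_hrpos_given_neg: float = 0.787
    pcr_prob: dict = field(default_factory=_default_pcr_prob)
    tumor_size_probs: dict = field(
        default_factory=lambda: {"0-1": 0.0, ">1-2": 0.01, ">2-5": 0.62, ">5": 0.37}
    )
    p_size_missing: float = 3 / 116
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_experimental", "n_control"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v}")
        for name in ("p_biomarker_pos", "p_hrpos_given_pos", "p_hrpos_given_neg", "p_size_missing"):
            _check_prob(getattr(self, name), name)
        cells = {(a, b) for a in ("control", "experimental") for b in ("negative", "positive")}
        if set(self.pcr_prob) != cells:
            raise ValidationError(
                f"pcr_prob must have exactly the 4 cells {sorted(cells)}, got {sorted(self.pcr_prob)}"
            )
        for key, p in self.pcr_prob.items():
            _check_prob(p, f"pcr_prob[{key}]")
        total = sum(self.tumor_size_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"tumor_size_probs must sum to 1, got {total}")

    @property
    def generating_odds_ratios(self) -> dict:
        """Per-arm biomarker-response odds ratios implied by pcr_prob."""
        out = {}
        for arm in ("experimental", "control"):
            pp = self.pcr_prob[(arm, "positive")]
            pn = self.pcr_prob[(arm, "negative")]
            out[arm] = (pp / (1 - pp)) / (pn / (1 - pn))
        return out


def simulate_trial(config: TrialSimConfig) -> pd.DataFrame:
    """Draw a per-patient trial table (arm, biomarker, hr_status,
    tumor_size_cat, pcr), reproducible under the seed."""
    cfg = config
    rng = _rng(cfg.seed, "trial")
    n = cfg.n_experimental + cfg.n_control
    arm = np.array(["experimental"] * cfg.n_experimental + ["control"] * cfg.n_control)
    biomarker = np.where(rng.random(n) < cfg.p_biomarker_pos, "positive", "negative")
    p_hr = np.where(biomarker == "positive", cfg.p_hrpos_given_pos, cfg.p_hrpos_given_neg)
    hr_status = np.where(rng.random(n) < p_hr, "HR+", "TN")
    cats = list(cfg.tumor_size_probs)
    probs = np.array([cfg.tumor_size_probs[c] for c in cats])
    size = rng.choice(cats, size=n, p=probs / probs.sum()).astype(object)
    size[rng.random(n) < cfg.p_size_missing] = None
    p_pcr = np.array([cfg.pcr_prob[(a, b)] for a, b in zip(arm, biomarker)])
    pcr = (rng.random(n) < p_pcr).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "arm": arm,
            "biomarker": biomarker,
            "hr_status": hr_status,
            "tumor_size_cat": size,
            "pcr": pcr,
        }
    ).set_index("patient_id")
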