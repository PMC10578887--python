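"""Synthetic ADNI-like cohort generation with known ground truth.

The generator draws latent Bernoulli disease states (AD pathology, vascular
disease) per subject and shifts biomarker distributions accordingly:

* CSF Aβ42 and pTau are log-normal; the AD state lowers Aβ42 and raises
  pTau (negatively correlated through a shared amyloid/tau latent factor).
* mFW and PSMD are log-normal and positively correlated through a shared
  white-matter-injury factor; the VD state raises both.
* The memory and executive composites are linear in the latent states,
  an impairment indicator, and covariates, plus Gaussian noise; the AD
  state hits memory harder, the VD state hits executive function harder.

Cognitive impairment is itself a latent Bernoulli whose probability rises
with each disease state, so the cohort contains the full eight-group
structure, including preclinical subjects (disease factors with intact
cognition) and cognitively low subjects without either factor.

Latent truths are returned alongside the biomarker table, so recovery of
the trichotomy labels by the full pipeline can be tested without any real
data. Defaults make the cohort composition resemble a memory-clinic
research cohort: ≈40% AD-factor-positive, ≈18% vascular-positive, ≈45%
cognitively impaired among the diseased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortGeneratorConfig",
    "strong_effect_config",
    "generate_cohort",
    "generate_two_group_features",
]


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Parameters of the latent-state cohort generator.

    Biomarker locations/scales are on the modeling scale: log10 for Aβ42,
    pTau (pg/mL), mFW (scaled ×1e2) and PSMD (scaled ×1e4); linear
    (standardized units) for the cognition composites. Effect sizes are
    additive shifts on those scales under the corresponding latent state.
    """

    n_subjects: int = 500
    seed: int = 0

    prevalence_ad: float = 0.40
    prevalence_vd: float = 0.18

    # healthy-state location (log10 scale for biomarkers)
    mean_log_abeta42: float = 3.15   # ≈1400 pg/mL
    mean_log_ptau: float = 1.26      # ≈18 pg/mL
    mean_log_mfw_x100: float = 1.20  # mFW ≈ 0.16
    mean_log_psmd_x1e4: float = 0.30  # PSMD ≈ 2e-4 mm²/s

    sd_log_abeta42: float = 0.12
    sd_log_ptau: float = 0.15
    sd_log_mfw_x100: float = 0.08
    sd_log_psmd_x1e4: float = 0.12

    # AD-state shifts (log10): Aβ42 down, pTau up
    effect_ad_abeta42: float = -0.30
    effect_ad_ptau: float = 0.30
    # VD-state shifts (log10): both white-matter markers up
    effect_vd_mfw: float = 0.30
    effect_vd_psmd: float = 0.35

    # within-pair coupling through shared latent factors (fraction of SD)
    rho_csf: float = 0.4
    rho_wm: float = 0.7
    rho_cog: float = 0.5

    # cognition model (standardized units)
    base_mem: float = 1.0
    base_ef: float = 0.9
    impairment_drop_mem: float = 1.8
    impairment_drop_ef: float = 1.6
    coupling_ad_mem: float = 0.3   # additional memory drop when AD-positive
    coupling_ad_ef: float = 0.1
    coupling_vd_mem: float = 0.1
    coupling_vd_ef: float = 0.3    # additional executive drop when VD-positive
    noise_sd_cog: float = 0.35

    # impairment probability: base + per-state increments (clipped to [0,1])
    p_impaired_base: float = 0.15
    p_impaired_ad: float = 0.55
    p_impaired_vd: float = 0.30

    # covariates
    mean_age: float = 72.0
    sd_age: float = 7.0
    p_male: float = 0.49
    mean_education: float = 16.4
    sd_education: float = 2.5
    protocols: tuple = ("ADNI2", "ADNI3")
    protocol_probs: tuple = (0.5, 0.5)
    age_slope_cog: float = -0.01  # per year above the cohort mean

    def __post_init__(self) -> None:
        for name in ("prevalence_ad", "prevalence_vd", "p_male",
                     "p_impaired_base", "p_impaired_ad", "p_impaired_vd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("sd_log_abeta42", "sd_log_ptau", "sd_log_mfw_x100",
                     "sd_log_psmd_x1e4", "noise_sd_cog", "sd_age", "sd_education"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.protocols) != len(self.protocol_probs):
            raise ValueError("protocols and protocol_probs must align")

    def with_(self, **kwargs) -> "CohortGeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def strong_effect_config(n_subjects: int = 2000, seed: int = 0) -> CohortGeneratorConfig:
    """Configuration with well-separated disease states (shifts >= 2 SD on
    every composite axis), used for end-to-end label-recovery checks where
    the latent truth should dominate the noise."""
    return CohortGeneratorConfig(
        n_subjects=n_subjects,
        seed=seed,
        mean_log_abeta42=3.20,
        mean_log_ptau=1.20,
        sd_log_abeta42=0.10,
        sd_log_ptau=0.12,
        effect_ad_abeta42=-0.50,
        effect_ad_ptau=0.50,
        effect_vd_mfw=0.45,
        effect_vd_psmd=0.50,
        coupling_ad_mem=0.15,
        coupling_ad_ef=0.05,
        coupling_vd_mem=0.05,
        coupling_vd_ef=0.15,
        noise_sd_cog=0.30,
    )


def _correlated_pair(rng, n, rho):
    """Two standard-normal vectors with correlation ``rho`` via a shared factor."""
    shared = rng.standard_normal(n)
    a = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    b = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    return a, b


def generate_cohort(config: CohortGeneratorConfig) -> tuple:
    """Draw a synthetic cohort table and its latent-truth table.

    Returns ``(cohort, truth)``: ``cohort`` follows the standard input
    schema (subject_id, abeta42, ptau, mfw, psmd, adni_mem, adni_ef, age,
    sex, education, protocol, apoe4, cdrsb, delta_cdrsb, hv, ba,
    clinical_label); ``truth`` records the latent states (ad, vd, impaired)
    per subject. Fully reproducible given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    ad = rng.random(n) < cfg.prevalence_ad
    vd = rng.random(n) < cfg.prevalence_vd
    p_imp = np.clip(
        cfg.p_impaired_base
        + cfg.p_impaired_ad * ad
        + cfg.p_impaired_vd * vd,
        0.0,
        1.0,
    )
    impaired = rng.random(n) < p_imp

    # CSF pair: anti-correlated on the (−Aβ42, pTau) axes
    za, zt = _correlated_pair(rng, n, cfg.rho_csf)
    log_abeta = cfg.mean_log_abeta42 - cfg.sd_log_abeta42 * za + cfg.effect_ad_abeta42 * ad
    log_ptau = cfg.mean_log_ptau + cfg.sd_log_ptau * zt + cfg.effect_ad_ptau * ad

    zm, zp = _correlated_pair(rng, n, cfg.rho_wm)
    log_mfw = cfg.mean_log_mfw_x100 + cfg.sd_log_mfw_x100 * zm + cfg.effect_vd_mfw * vd
    log_psmd = cfg.mean_log_psmd_x1e4 + cfg.sd_log_psmd_x1e4 * zp + cfg.effect_vd_psmd * vd

    age = rng.normal(cfg.mean_age, cfg.sd_age, n)
    sex = np.where(rng.random(n) < cfg.p_male, "male", "female")
    education = np.clip(rng.normal(cfg.mean_education, cfg.sd_education, n), 8, 24)
    protocol = rng.choice(cfg.protocols, size=n, p=cfg.protocol_probs)

    em, ee = _correlated_pair(rng, n, cfg.rho_cog)
    age_term = cfg.age_slope_cog * (age - cfg.mean_age)
    adni_mem = (
        cfg.base_mem
        - cfg.impairment_drop_mem * impaired
        - cfg.coupling_ad_mem * ad
        - cfg.coupling_vd_mem * vd
        + age_term
        + cfg.noise_sd_cog * em
    )
    adni_ef = (
        cfg.base_ef
        - cfg.impairment_drop_ef * impaired
        - cfg.coupling_ad_ef * ad
        - cfg.coupling_vd_ef * vd
        + age_term
        + cfg.noise_sd_cog * ee
    )

    # auxiliary variables, coupled to the latent states
    p_apoe = np.clip(0.15 + 0.40 * ad, 0, 1)
    apoe_draw = rng.random((n, 2))
    apoe4 = (apoe_draw < p_apoe[:, None]).sum(axis=1)
    cdrsb = np.round(
        np.clip(rng.normal(0.3 + 2.5 * impaired + 0.8 * ad, 0.8), 0, 18) * 2
    ) / 2
    delta_cdrsb = rng.normal(0.1 + 0.8 * (impaired & ad) + 0.3 * impaired, 0.4)
    hv = rng.normal(7400 - 900 * ad - 500 * impaired, 600)
    ba = rng.normal(0.0 + 0.5 * impaired + 0.3 * vd, 0.6)

    # impaired subjects split into MCI vs dementia by clinical severity;
    # the 4.0 CDRSB cut keeps the impaired stratum MCI-dominated
    clinical = np.where(
        ~impaired, "aCN", np.where(cdrsb >= 4.0, "aAD", "aMCI")
    )

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "abeta42": 10.0 ** log_abeta,
            "ptau": 10.0 ** log_ptau,
            "mfw": 10.0 ** log_mfw / 1e2,
            "psmd": 10.0 ** log_psmd / 1e4,
            "adni_mem": adni_mem,
            "adni_ef": adni_ef,
            "age": age,
            "sex": sex,
            "education": education,
            "protocol": protocol,
            "apoe4": apoe4,
            "cdrsb": cdrsb,
            "delta_cdrsb": delta_cdrsb,
            "hv": hv,
            "ba": ba,
            "clinical_label": clinical,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "ad": ad.astype(int),
            "vd": vd.astype(int),
            "impaired": impaired.astype(int),
        }
    )
    return cohort, truth


def generate_two_group_features(
    n_per_class: int,
    mean_shift,
    covariance=None,
    seed: int = 0,
) -> tuple:
    """Two Gaussian classes for discriminant-axis recovery tests.

    Controls are centered at the origin, patients at ``mean_shift``; both
    share ``covariance`` (identity by default). Returns ``(features,
    labels)`` with labels 1 for the shifted (patient) class.
    """
    rng = np.random.default_rng(seed)
    shift = np.asarray(mean_shift, dtype=float)
    p = shift.size
    if covariance is None:
        covariance = np.eye(p)
    cov = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("covariance must be positive definite") from None
    z = rng.standard_normal((2 * n_per_class, p)) @ chol.T
    z[n_per_class:] += shift
    labels = np.repeat([0, 1], n_per_class)
    return z, labels
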