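"""Synthetic rapid-autopsy cohort generator with known ground truth.

Emulates the statistical structure of a multi-site metastatic prostate
cancer autopsy cohort: ~52 patients with a median of 11 tumor samples each
(range 2-37); dominant-subtype prevalences 65/23/8/4% for AR+/NE-,
AR-/NE+, AR+/NE+ and AR-/NE-; within-patient subtype admixture drawn from
a Dirichlet-multinomial so that roughly 70% of patients are heterogeneous;
anatomic sites whose NE-positive odds vs bone follow configurable odds
ratios (defaults 4.8 liver, 3.6 lymph node, 7.8 abdominal soft tissue);
subtype-conditional Ki-67 laws (Beta, medians 20/60/30/30%); patient-level
genomic alteration flags with an overall AR-alteration rate of ~54% and
lower subtype mixing in AR-altered patients; and clinical milestone
timelines with subtype-dependent bone-metastasis-to-death medians.

Every generated cohort ships with its generating parameters and
per-patient truths so parameter-recovery tests need no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .heterogeneity import expected_hi_dirichlet_multinomial, subtype_hi
from .ihc import SITES, SUBTYPE_LABELS

_L = SUBTYPE_LABELS  # ("AR+/NE-", "AR-/NE+", "AR+/NE+", "AR-/NE-")

DEFAULT_PREVALENCE = {_L[0]: 0.65, _L[1]: 0.23, _L[2]: 0.08, _L[3]: 0.04}

# admixture affinities: given a dominant subtype, how the non-dominant
# mixing mass splits over the other subtypes (AR+/NE- patients co-occur
# mostly with AR+/NE+)
DEFAULT_AFFINITY = {
    _L[0]: {_L[2]: 0.70, _L[1]: 0.20, _L[3]: 0.10},
    _L[1]: {_L[2]: 0.50, _L[0]: 0.35, _L[3]: 0.15},
    _L[2]: {_L[0]: 0.70, _L[1]: 0.20, _L[3]: 0.10},
    _L[3]: {_L[0]: 0.50, _L[1]: 0.30, _L[2]: 0.20},
}

DEFAULT_SITE_PROBS = {
    "bone": 0.40,
    "liver": 0.15,
    "lymph_node": 0.15,
    "lung": 0.06,
    "prostate": 0.10,
    "abdominal_soft_tissue": 0.08,
    "thoracic_soft_tissue": 0.04,
    "other": 0.02,
}

DEFAULT_NE_SITE_LOG_OR = {
    "liver": float(np.log(4.8)),
    "lymph_node": float(np.log(3.6)),
    "abdominal_soft_tissue": float(np.log(7.8)),
}

DEFAULT_KI67_MEDIANS = {_L[0]: 20.0, _L[1]: 60.0, _L[2]: 30.0, _L[3]: 30.0}

# per-dominant alteration probabilities; chosen so the prevalence-weighted
# AR-alteration rate is ~0.54 and RB1/TP53 losses are enriched in AR-/NE+
DEFAULT_GENOMIC_RATES = {
    "AR": {_L[0]: 0.62, _L[1]: 0.35, _L[2]: 0.62, _L[3]: 0.20},
    "RB1": {_L[0]: 0.22, _L[1]: 0.70, _L[2]: 0.22, _L[3]: 0.22},
    "TP53": {_L[0]: 0.43, _L[1]: 0.65, _L[2]: 0.43, _L[3]: 0.43},
    "PTEN": {_L[0]: 0.43, _L[1]: 0.43, _L[2]: 0.43, _L[3]: 0.60},
    "BRCA2": {_L[0]: 0.10, _L[1]: 0.10, _L[2]: 0.10, _L[3]: 0.10},
    "CHD1": {_L[0]: 0.08, _L[1]: 0.08, _L[2]: 0.08, _L[3]: 0.08},
}

DEFAULT_BONE_TO_DEATH_MEDIANS = {_L[0]: 2.7, _L[1]: 1.9, _L[2]: 7.9, _L[3]: 0.9}


@dataclass
class SyntheticCohortConfig:
    """Generative parameters of the synthetic cohort."""

    n_patients: int = 52
    # samples per patient: rounded lognormal, clipped
    samples_median: float = 11.0
    samples_sigma: float = 0.62
    samples_min: int = 2
    samples_max: int = 37
    cores_per_sample: int = 2
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    # Dirichlet-multinomial mixing: alpha = concentration * mixture where
    # mixture puts dominant_mass on the dominant subtype
    dominant_mass: float = 0.75
    dominant_mass_ar_altered: float = 0.88
    concentration: float = 10.0
    affinity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AFFINITY.items()}
    )
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROBS)
    )
    ne_site_log_or: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NE_SITE_LOG_OR)
    )
    ki67_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KI67_MEDIANS)
    )
    ki67_concentration: float = 5.0
    # samples scatter around a patient-level Ki-67 center so that Ki-67
    # positivity is correlated within a patient, keeping the cohort mean
    # Ki-67 heterogeneity index well below the independence maximum
    ki67_sample_concentration: float = 8.0
    ki67_core_sd: float = 5.0
    # H-score laws: positive markers on [20, 200], negative on [0, 19]
    hscore_pos_mode: float = 150.0
    hscore_pos_sd: float = 40.0
    hscore_neg_mode: float = 5.0
    hscore_neg_sd: float = 5.0
    boundary_flip_prob: float = 0.0   # flips marker positivity across 20
    genomic_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_GENOMIC_RATES.items()}
    )
    n_metastases_sequenced: int = 3
    divergent_event_prob: float = 0.05
    n_no_genomics: int = 6
    bone_to_death_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BONE_TO_DEATH_MEDIANS)
    )
    duration_sigma: float = 0.6
    seed: int = 17

    def __post_init__(self) -> None:
        pv = np.array([self.prevalence[lab] for lab in _L])
        if np.any(pv < 0) or not np.isclose(pv.sum(), 1.0):
            raise ValueError("prevalence vector must be non-negative and sum to 1")
        for p in self.site_probs.values():
            if not (0 <= p <= 1):
                raise ValueError("site probabilities must be in [0, 1]")
        if not (0 < self.dominant_mass < 1):
            raise ValueError("dominant_mass must be in (0, 1)")

    def mixing_alpha(self, dominant: str, ar_altered: bool = False) -> np.ndarray:
        """DM parameter vector over the four subtypes for one patient."""
        m = self.dominant_mass_ar_altered if ar_altered else self.dominant_mass
        mix = np.empty(4)
        for i, lab in enumerate(_L):
            if lab == dominant:
                mix[i] = m
            else:
                mix[i] = (1.0 - m) * self.affinity[dominant][lab]
        return self.concentration * mix / mix.sum()

    def expected_hi(self, dominant: str, ar_altered: bool = False) -> float:
        return expected_hi_dirichlet_multinomial(self.mixing_alpha(dominant, ar_altered))


def _beta_params_for_median(median_pct: float, nu: float) -> tuple[float, float]:
    """Beta(a, nu-a) with the requested median on the 0-100 scale."""
    target = median_pct / 100.0

    def f(a: float) -> float:
        return stats.beta.ppf(0.5, a, nu - a) - target

    a = optimize.brentq(f, 1e-3, nu - 1e-3)
    return a, nu - a


def _draw_n_samples(cfg: SyntheticCohortConfig, rng: np.random.Generator, size: int):
    n = np.round(rng.lognormal(np.log(cfg.samples_median), cfg.samples_sigma, size))
    return np.clip(n.astype(int), cfg.samples_min, cfg.samples_max)


def _draw_hscore(rng, positive: bool, cfg: SyntheticCohortConfig) -> int:
    if positive:
        lo, hi, mode, sd = 20.0, 200.0, cfg.hscore_pos_mode, cfg.hscore_pos_sd
    else:
        lo, hi, mode, sd = 0.0, 19.0, cfg.hscore_neg_mode, cfg.hscore_neg_sd
    a, b = (lo - mode) / sd, (hi - mode) / sd
    v = stats.truncnorm.rvs(a, b, loc=mode, scale=sd, random_state=rng)
    return int(np.clip(round(v), lo, hi))


def _site_probs_given_ne(cfg: SyntheticCohortConfig, ne: bool) -> np.ndarray:
    """Categorical site law conditional on NE status.

    Sampling sites from q_site * exp(ne * logOR_site) (normalized) makes
    the marginal odds ratio of NE positivity for each site vs bone equal
    exactly to the configured OR.
    """
    q = np.array([cfg.site_probs.get(s, 0.0) for s in SITES])
    if ne:
        lor = np.array([cfg.ne_site_log_or.get(s, 0.0) for s in SITES])
        q = q * np.exp(lor)
    return q / q.sum()


def generate_patient_labels(
    cfg: SyntheticCohortConfig, rng: np.random.Generator
) -> tuple[str, bool, np.ndarray, list[str]]:
    """Draw one patient's dominant subtype, AR flag, DM alpha, and labels."""
    prev = np.array([cfg.prevalence[lab] for lab in _L])
    dominant = _L[rng.choice(4, p=prev)]
    ar_altered = rng.random() < cfg.genomic_rates["AR"][dominant]
    alpha = cfg.mixing_alpha(dominant, ar_altered)
    p = rng.dirichlet(alpha)
    n = int(_draw_n_samples(cfg, rng, 1)[0])
    labels = [_L[i] for i in rng.choice(4, size=n, p=p)]
    return dominant, ar_altered, alpha, labels


def generate_cohort(
    cfg: SyntheticCohortConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (sample table, genomic table, clinical table, ground truth).

    The sample table is the long per-core format the IHC readers consume
    (one row per core x marker, Ki-67 included as marker "Ki67"); the
    genomic table has one row per metastasis x gene with PACN and
    annotations; the clinical table has day-offset milestones. Ground
    truth records the generating parameters and per-patient truths.
    Deterministic given the seed.
    """
    cfg = cfg or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    beta_params = {
        lab: _beta_params_for_median(m, cfg.ki67_concentration)
        for lab, m in cfg.ki67_medians.items()
    }
    site_p = {ne: _site_probs_given_ne(cfg, ne) for ne in (False, True)}

    sample_rows: list[dict] = []
    genomic_rows: list[dict] = []
    clinical_rows: list[dict] = []
    truth_patients: dict[str, dict] = {}

    no_genomics = set(
        rng.choice(cfg.n_patients, size=min(cfg.n_no_genomics, cfg.n_patients),
                   replace=False)
    )

    for ip in range(cfg.n_patients):
        pid = f"P{ip + 1:03d}"
        dominant, ar_altered, alpha, labels = generate_patient_labels(cfg, rng)
        n = len(labels)

        # patient-level Ki-67 centers, one per subtype the patient may carry
        ki67_centers = {
            lab: float(np.clip(rng.beta(*beta_params[lab]), 1e-4, 1 - 1e-4))
            for lab in _L
        }

        # genomic flags
        flags = {"AR": ar_altered}
        for gene in ("RB1", "TP53", "PTEN", "BRCA2", "CHD1"):
            flags[gene] = bool(rng.random() < cfg.genomic_rates[gene][dominant])

        # per-sample sites and IHC cores
        for isamp, lab in enumerate(labels):
            ar_pos = lab.startswith("AR+")
            ne_pos = lab.endswith("NE+")
            site = SITES[rng.choice(len(SITES), p=site_p[ne_pos])]
            block = f"{pid}-B{isamp + 1:02d}"
            # marker positivity pattern consistent with the subtype
            if ar_pos:
                ar_m = rng.random() < 0.95
                nkx_m = rng.random() < 0.90
                if not (ar_m or nkx_m):
                    ar_m = True
            else:
                ar_m = nkx_m = False
            if ne_pos:
                syp_m = rng.random() < 0.85
                insm_m = rng.random() < 0.90
                if not (syp_m or insm_m):
                    insm_m = True
            else:
                syp_m = insm_m = False
            ks = cfg.ki67_sample_concentration
            center = ki67_centers[lab]
            sample_ki67 = 100.0 * rng.beta(center * ks, (1.0 - center) * ks)
            for icore in range(cfg.cores_per_sample):
                core = f"C{icore + 1}"
                for marker, pos in (("AR", ar_m), ("NKX3.1", nkx_m),
                                    ("SYP", syp_m), ("INSM1", insm_m)):
                    eff_pos = pos
                    if cfg.boundary_flip_prob and rng.random() < cfg.boundary_flip_prob:
                        eff_pos = not pos
                    sample_rows.append({
                        "patient_id": pid, "site": site, "block_id": block,
                        "core_id": core, "marker": marker,
                        "value": _draw_hscore(rng, eff_pos, cfg),
                    })
                ki = float(np.clip(sample_ki67 + rng.normal(0, cfg.ki67_core_sd),
                                   0, 100))
                sample_rows.append({
                    "patient_id": pid, "site": site, "block_id": block,
                    "core_id": core, "marker": "Ki67", "value": round(ki, 1),
                })

        # genomic table: shared events across sequenced metastases
        if ip not in no_genomics:
            n_mets = min(cfg.n_metastases_sequenced, n)
            for gene, altered in flags.items():
                gain_gene = gene == "AR"
                divergent = altered and rng.random() < cfg.divergent_event_prob
                carrier = rng.integers(0, n_mets) if divergent else -1
                biallelic = altered and not gain_gene and rng.random() < 0.6
                mutation = (
                    "gain_of_function" if gain_gene and altered and rng.random() < 0.3
                    else ("loss_of_function" if altered and not gain_gene
                          and rng.random() < 0.3 else "")
                )
                for im in range(n_mets):
                    present = altered and (not divergent or im == carrier)
                    if present:
                        if gain_gene:
                            pacn = float(rng.uniform(2.6, 6.0))
                        elif biallelic:
                            pacn = 0.0
                        else:
                            pacn = float(rng.uniform(0.1, 0.5))
                    else:
                        pacn = float(rng.uniform(0.8, 1.4))
                    genomic_rows.append({
                        "patient_id": pid, "metastasis_id": f"{pid}-M{im + 1}",
                        "gene": gene, "pacn": round(pacn, 3),
                        "mutation_class": mutation if present else "",
                        "biallelic": bool(biallelic and present),
                    })

        # clinical milestones (days; diagnosis at day 0)
        med_b = cfg.bone_to_death_medians[dominant]
        bone_to_death = rng.lognormal(np.log(med_b), cfg.duration_sigma)
        adt_to_death = bone_to_death * rng.lognormal(np.log(3.5 / 2.2), 0.3)
        dx_to_death = adt_to_death * rng.lognormal(np.log(5.3 / 3.5), 0.3)
        death = dx_to_death * 365.25
        adt = death - adt_to_death * 365.25
        bone = death - bone_to_death * 365.25
        crpc = bone + rng.uniform(0.1, 0.6) * (death - bone)
        psa_scale = 50.0 if dominant in (_L[0], _L[2]) else 2.0
        clinical_rows.append({
            "patient_id": pid,
            "diagnosis_day": 0.0,
            "adt_start_day": round(max(adt, 0.0), 1),
            "first_bone_met_day": round(max(bone, adt, 0.0), 1),
            "castration_resistance_day": round(max(crpc, bone, 0.0), 1),
            "death_day": round(death, 1),
            "last_psa": round(float(rng.lognormal(np.log(psa_scale), 1.0)), 2),
        })

        counts = {lab: labels.count(lab) for lab in _L}
        truth_patients[pid] = {
            "dominant": dominant,
            "n_samples": n,
            "true_label_counts": counts,
            "true_hi": subtype_hi(counts).value,
            "expected_hi": expected_hi_dirichlet_multinomial(alpha),
            "genomic_flags": flags,
            "has_genomics": ip not in no_genomics,
            "bone_to_death_median": med_b,
        }

    ground_truth = {
        "config": _config_dict(cfg),
        "expected_hi_by_dominant": {
            lab: cfg.expected_hi(lab) for lab in _L
        },
        "patients": truth_patients,
    }
    return (
        pd.DataFrame(sample_rows),
        pd.DataFrame(genomic_rows),
        pd.DataFrame(clinical_rows),
        ground_truth,
    )


def _config_dict(cfg: SyntheticCohortConfig) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d))  # plain JSON types


def expected_heterogeneous_fraction(
    cfg: SyntheticCohortConfig, max_n: int | None = None
) -> float:
    """Expected fraction of patients with >1 observed subtype.

    Uses the exact DM all-same-category probability, averaged over the
    samples-per-patient law (evaluated on a dense grid) and the dominant
    prevalence. Ignores H-score noise, so it is the label-level truth.
    """
    max_n = max_n or cfg.samples_max
    # discretized lognormal sample-size law
    ns = np.arange(cfg.samples_min, max_n + 1)
    edges = np.concatenate([[0.5 + cfg.samples_min - 1], ns + 0.5])
    cdf = stats.lognorm.cdf(edges, s=cfg.samples_sigma, scale=cfg.samples_median)
    pn = np.diff(cdf)
    pn[0] += cdf[0]          # clipping mass below
    pn[-1] += 1 - cdf[-1]    # clipping mass above
    pn = pn / pn.sum()

    p_hom = 0.0
    for lab in _L:
        prev = cfg.prevalence[lab]
        for ar_altered, p_ar in (
            (True, cfg.genomic_rates["AR"][lab]),
            (False, 1 - cfg.genomic_rates["AR"][lab]),
        ):
            alpha = cfg.mixing_alpha(lab, ar_altered)
            A = alpha.sum()
            for n, w in zip(ns, pn):
                i = np.arange(n)
                ph = float(sum(np.prod((a + i) / (A + i)) for a in alpha))
                p_hom += prev * p_ar * w * ph
    return 1.0 - p_hom


def recover_parameters(
    sample_table: pd.DataFrame,
    genomic_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    ground_truth: dict,
    seed: int = 0,
) -> dict:
    """Run the full pipeline on a generated cohort and compare to truth.

    Reports the recovered dominant-subtype distribution, per-sample label
    recovery, mean subtype HI vs the DM expectation, Ki-67 medians by
    subtype, the liver NE odds ratio, and the direction of the HI vs
    AR-alteration association.
    """
    from . import io as io_mod
    from .associations import median_diff_ci, ne_site_model

    res = io_mod.analyze_cohort(sample_table, genomic_table, clinical_table,
                                seed=seed)
    patients = res["patient_summary"]
    samples = res["sample_table"]

    truth = ground_truth["patients"]
    dominant_true = {p: t["dominant"] for p, t in truth.items()}
    dom_match = float(np.mean([
        patients.loc[patients.patient_id == p, "dominant"].iloc[0] == d
        for p, d in dominant_true.items()
    ]))
    dom_dist = patients["dominant"].value_counts(normalize=True).to_dict()

    # per-sample label recovery
    true_counts_total = {lab: 0 for lab in _L}
    for t in truth.values():
        for lab, c in t["true_label_counts"].items():
            true_counts_total[lab] += c
    obs_counts = samples["subtype"].value_counts().to_dict()

    hi_mean = float(patients.loc[patients.hi_defined, "hi"].mean())
    expected_hi = float(np.mean([t["expected_hi"] for t in truth.values()]))

    ki67_medians = (
        samples.groupby("subtype")["ki67"].median().to_dict()
    )

    model = ne_site_model(samples)
    liver_or = model.odds_ratios.get("liver", float("nan"))
    liver_ci = model.or_ci.get("liver", (float("nan"), float("nan")))

    # HI by AR-alteration status (generator truth flags)
    ar_by_pid = {p: t["genomic_flags"]["AR"] for p, t in truth.items()}
    hi_def = patients.loc[patients.hi_defined]
    hi_alt = hi_def.loc[hi_def.patient_id.map(ar_by_pid).astype(bool), "hi"]
    hi_wt = hi_def.loc[~hi_def.patient_id.map(ar_by_pid).astype(bool), "hi"]
    hi_ar_assoc = None
    if len(hi_alt) >= 2 and len(hi_wt) >= 2:
        cmp = median_diff_ci(hi_alt.tolist(), hi_wt.tolist())
        hi_ar_assoc = {"median_diff": cmp.estimate, "p": cmp.p_value}

    return {
        "dominant_accuracy": dom_match,
        "dominant_distribution": dom_dist,
        "true_label_totals": true_counts_total,
        "observed_label_totals": obs_counts,
        "mean_hi": hi_mean,
        "expected_hi": expected_hi,
        "ki67_medians_by_subtype": ki67_medians,
        "liver_or": liver_or,
        "liver_or_ci": liver_ci,
        "glmm_sigma": model.sigma,
        "hi_ar_alteration": hi_ar_assoc,
    }
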