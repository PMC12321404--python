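"""IHC data model and AR/NE molecular subtype classification.

Tumors are typed on four immunohistochemical markers scored with the
two-level H-score system (0-200): AR and NKX3.1 read out androgen-receptor
axis activity, SYP and INSM1 read out neuroendocrine differentiation.
A sample is AR+ if AR and/or NKX3.1 reaches H-score >= 20, NE+ if SYP
and/or INSM1 reaches H-score >= 20, yielding four subtypes: AR+/NE-
(prostatic adenocarcinoma), AR-/NE+ (neuroendocrine prostate cancer),
AR+/NE+ (amphicrine or mixed/biphenotypic), and AR-/NE- (double negative).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

HSCORE_MIN = 0
HSCORE_MAX = 200
HSCORE_POSITIVITY_THRESHOLD = 20.0
AMPHICRINE_COEXPRESSION_THRESHOLD = 0.70

AR_MARKERS = ("AR", "NKX3.1")
NE_MARKERS = ("SYP", "INSM1")
REQUIRED_MARKERS = AR_MARKERS + NE_MARKERS
OPTIONAL_MARKERS = ("ASCL1", "SOX2", "FOXA2")

AR_POS_NE_NEG = "AR+/NE-"
AR_NEG_NE_POS = "AR-/NE+"
AR_POS_NE_POS = "AR+/NE+"
AR_NEG_NE_NEG = "AR-/NE-"

# cohort prevalence order; also the dominant-subtype tie-break priority
SUBTYPE_LABELS = (AR_POS_NE_NEG, AR_NEG_NE_POS, AR_POS_NE_POS, AR_NEG_NE_NEG)

SITES = (
    "bone",
    "liver",
    "lymph_node",
    "lung",
    "prostate",
    "abdominal_soft_tissue",
    "thoracic_soft_tissue",
    "other",
)


def normalize_site(site: str) -> str:
    """Map a free-text anatomic site onto the controlled vocabulary.

    Unknown sites are coerced to ``"other"`` with a warning.
    """
    s = str(site).strip().lower().replace(" ", "_").replace("-", "_")
    if s in SITES:
        return s
    warnings.warn(f"unknown anatomic site {site!r} mapped to 'other'", stacklevel=2)
    return "other"


def _check_hscore(marker: str, value: float) -> float:
    v = float(value)
    if not (HSCORE_MIN <= v <= HSCORE_MAX):
        raise ValueError(f"H-score for {marker} must be in [0, 200], got {value}")
    return v


@dataclass(frozen=True)
class CoreMeasurement:
    """One TMA core: marker H-scores plus Ki-67 percent positivity."""

    patient_id: str
    site: str
    block_id: str
    hscores: Mapping[str, float]
    ki67: float | None = None
    core_id: str = ""

    def __post_init__(self) -> None:
        for marker, value in self.hscores.items():
            _check_hscore(marker, value)
        if self.ki67 is not None and not (0 <= self.ki67 <= 100):
            raise ValueError(f"Ki-67 must be in [0, 100], got {self.ki67}")


@dataclass(frozen=True)
class SubtypeCall:
    ar_positive: bool
    ne_positive: bool

    @property
    def label(self) -> str:
        if self.ar_positive:
            return AR_POS_NE_POS if self.ne_positive else AR_POS_NE_NEG
        return AR_NEG_NE_POS if self.ne_positive else AR_NEG_NE_NEG


@dataclass(frozen=True)
class TumorSample:
    """A tissue-block-level tumor sample aggregated over its cores."""

    patient_id: str
    site: str
    block_id: str
    cores: tuple[CoreMeasurement, ...]
    combined_hscores: Mapping[str, float] = field(default_factory=dict)
    combined_ki67: float | None = None

    @classmethod
    def from_cores(
        cls, cores: Sequence[CoreMeasurement], method: str = "max"
    ) -> "TumorSample":
        hscores, ki67 = combine_cores(cores, method=method)
        first = cores[0]
        return cls(
            patient_id=first.patient_id,
            site=first.site,
            block_id=first.block_id,
            cores=tuple(cores),
            combined_hscores=hscores,
            combined_ki67=ki67,
        )

    def subtype(self) -> SubtypeCall:
        return classify_sample(self.combined_hscores)


def combine_cores(
    cores: Sequence[CoreMeasurement], method: str = "max"
) -> tuple[dict[str, float], float | None]:
    """Aggregate per-core H-scores and Ki-67 to sample level.

    ``method="max"`` (default) calls a sample positive if any sampled
    region is positive, which mirrors multi-region sampling of
    morphologically distinct blocks; ``"mean"`` averages instead. Markers
    absent from every core stay missing; markers present in only some
    cores are aggregated over the cores that measured them.
    """
    if len(cores) == 0:
        raise ValueError("combine_cores requires at least one core")
    keys = {(c.patient_id, c.site, c.block_id) for c in cores}
    if len(keys) > 1:
        raise ValueError(f"cores span multiple samples: {sorted(keys)}")
    if method not in ("max", "mean"):
        raise ValueError(f"unknown combination method {method!r}")

    agg = max if method == "max" else (lambda v: sum(v) / len(v))
    markers = {m for c in cores for m in c.hscores}
    combined = {
        m: float(agg([c.hscores[m] for c in cores if m in c.hscores]))
        for m in sorted(markers)
    }
    ki67_vals = [c.ki67 for c in cores if c.ki67 is not None]
    ki67 = float(agg(ki67_vals)) if ki67_vals else None
    return combined, ki67


def classify_sample(
    hscores: Mapping[str, float],
    threshold: float = HSCORE_POSITIVITY_THRESHOLD,
) -> SubtypeCall:
    """Classify a sample into one of the four AR/NE subtypes.

    AR+ iff AR or NKX3.1 H-score >= threshold; NE+ iff SYP or INSM1
    H-score >= threshold (inclusive at the threshold). All four markers
    must be present.
    """
    missing = [m for m in REQUIRED_MARKERS if m not in hscores or hscores[m] is None]
    if missing:
        raise ValueError(f"missing required marker(s) for subtyping: {', '.join(missing)}")
    for m in REQUIRED_MARKERS:
        _check_hscore(m, hscores[m])
    ar_positive = any(hscores[m] >= threshold for m in AR_MARKERS)
    ne_positive = any(hscores[m] >= threshold for m in NE_MARKERS)
    return SubtypeCall(ar_positive=ar_positive, ne_positive=ne_positive)


@dataclass(frozen=True)
class PatientSubtypeSummary:
    patient_id: str
    n_samples: int
    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    dominant: str
    dominant_tied: bool

    @property
    def heterogeneous(self) -> bool:
        """True if more than one subtype is observed in the patient."""
        return sum(1 for v in self.counts.values() if v > 0) > 1


def summarize_patient(
    samples: Sequence[TumorSample] | Sequence[str],
) -> PatientSubtypeSummary:
    """Patient-level subtype counts, fractions, and dominant subtype.

    Accepts TumorSample objects (classified on the fly) or pre-computed
    subtype labels paired with a patient id via `summarize_labels`. Ties
    for the dominant subtype are broken by cohort prevalence order
    (AR+/NE- > AR-/NE+ > AR+/NE+ > AR-/NE-) and flagged.
    """
    if len(samples) == 0:
        raise ValueError("summarize_patient requires at least one sample")
    if isinstance(samples[0], TumorSample):
        patients = {s.patient_id for s in samples}  # type: ignore[union-attr]
        if len(patients) > 1:
            raise ValueError(f"samples span multiple patients: {sorted(patients)}")
        patient_id = samples[0].patient_id  # type: ignore[union-attr]
        labels = [s.subtype().label for s in samples]  # type: ignore[union-attr]
    else:
        raise TypeError("summarize_patient expects TumorSample objects; "
                        "use summarize_labels for raw label lists")
    return summarize_labels(patient_id, labels)


def summarize_labels(patient_id: str, labels: Iterable[str]) -> PatientSubtypeSummary:
    """Summarize an explicit list of per-sample subtype labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("at least one label required")
    unknown = set(labels) - set(SUBTYPE_LABELS)
    if unknown:
        raise ValueError(f"unknown subtype label(s): {sorted(unknown)}")
    counts = Counter(labels)
    n = len(labels)
    full_counts = {lab: counts.get(lab, 0) for lab in SUBTYPE_LABELS}
    max_count = max(full_counts.values())
    winners = [lab for lab in SUBTYPE_LABELS if full_counts[lab] == max_count]
    return PatientSubtypeSummary(
        patient_id=patient_id,
        n_samples=n,
        counts=full_counts,
        fractions={lab: c / n for lab, c in full_counts.items()},
        dominant=winners[0],
        dominant_tied=len(winners) > 1,
    )


@dataclass(frozen=True)
class ArNePosSubLabel:
    """Sub-classification of AR+/NE+ tumors.

    Amphicrine carcinomas show coexpression of AR and NE markers in the
    same cells (>70% of tumor cells), whereas mixed/biphenotypic tumors
    are composed of distinct AR+/NE- and AR-/NE+ cell populations.
    """

    coexpression_fraction: float
    label: str


def classify_arne_pos_tumor(
    coexpression_fraction: float,
    threshold: float = AMPHICRINE_COEXPRESSION_THRESHOLD,
) -> ArNePosSubLabel:
    """Amphicrine iff the AR/NE coexpressing cell fraction exceeds 0.70 (strict)."""
    f = float(coexpression_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"coexpression fraction must be in [0, 1], got {f}")
    label = "amphicrine" if f > threshold else "mixed_biphenotypic"
    return ArNePosSubLabel(coexpression_fraction=f, label=label)
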