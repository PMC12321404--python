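"""Copy-number event calling and patient-level shared-alteration profiles.

Gene-level copy numbers arrive already adjusted for sample ploidy (PACN).
Events follow fixed thresholds: homozygous deletion at PACN = 0 (within a
small tolerance for real-valued estimates), deletion at PACN <= 0.5,
gain at PACN >= 1.5, amplification at PACN >= 2.5, otherwise neutral.
Point-mutation classes and biallelic status are consumed as annotations,
never called here. Patient-level profiles keep only alterations shared by
every assessed metastasis; genes altered in a strict subset are reported
as divergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

HOMDEL_TOLERANCE = 1e-6

EVENTS = ("homozygous_deletion", "deletion", "neutral", "gain", "amplification")

# severity used when collapsing across metastases: homozygous deletion
# dominates deletion, amplification dominates gain
_SEVERITY = {
    "neutral": 0,
    "gain": 1,
    "deletion": 1,
    "amplification": 2,
    "homozygous_deletion": 2,
}

DEFAULT_GENES = ("AR", "PTEN", "RB1", "TP53", "BRCA2", "CHD1")


def pacn_to_event(pacn: float, homdel_tol: float = HOMDEL_TOLERANCE) -> str:
    """Map a ploidy-adjusted copy number to its event category."""
    p = float(pacn)
    if p < 0:
        raise ValueError(f"PACN must be non-negative, got {pacn}")
    if p < homdel_tol:
        return "homozygous_deletion"
    if p <= 0.5:
        return "deletion"
    if p >= 2.5:
        return "amplification"
    if p >= 1.5:
        return "gain"
    return "neutral"


@dataclass(frozen=True)
class GeneCopyCall:
    gene: str
    pacn: float
    event: str

    @classmethod
    def from_pacn(cls, gene: str, pacn: float) -> "GeneCopyCall":
        return cls(gene=gene, pacn=float(pacn), event=pacn_to_event(pacn))


@dataclass(frozen=True)
class MetastasisGenomicProfile:
    patient_id: str
    metastasis_id: str
    copy_calls: Mapping[str, GeneCopyCall]
    mutation_classes: Mapping[str, str] = field(default_factory=dict)
    biallelic: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, call in self.copy_calls.items():
            if call.gene != gene:
                raise ValueError(f"copy call keyed {gene!r} carries gene {call.gene!r}")


@dataclass(frozen=True)
class PatientSharedProfile:
    """Per-gene alterations present in every assessed metastasis.

    ``shared_events`` holds the least severe event category observed for
    the gene across metastases (the alteration all metastases carry at
    minimum); ``divergent_genes`` lists genes altered in only a subset.
    """

    patient_id: str
    n_metastases: int
    shared_events: Mapping[str, str]
    divergent_genes: tuple[str, ...]
    shared_mutations: Mapping[str, str] = field(default_factory=dict)
    shared_biallelic: Mapping[str, bool] = field(default_factory=dict)


def shared_alterations(
    profiles: Sequence[MetastasisGenomicProfile],
) -> PatientSharedProfile:
    """Collapse per-metastasis profiles into the patient's shared profile.

    A gene's event is shared when every metastasis assessed for that gene
    shows a non-neutral event of the same direction; the reported category
    is the one guaranteed in all metastases (e.g. amplification in some
    and gain in others is shared as gain). Genes altered in a strict
    subset of metastases are divergent. Mutation classes and biallelic
    flags are shared only when identical across metastases.
    """
    if len(profiles) == 0:
        raise ValueError("at least one metastasis profile required")
    patients = {p.patient_id for p in profiles}
    if len(patients) > 1:
        raise ValueError(f"profiles span multiple patients: {sorted(patients)}")
    mets = {p.metastasis_id for p in profiles}
    if len(mets) != len(profiles):
        raise ValueError("duplicate metastasis_id in profiles")

    genes = sorted({g for p in profiles for g in p.copy_calls})
    shared: dict[str, str] = {}
    divergent: list[str] = []
    for gene in genes:
        events = [p.copy_calls[gene].event for p in profiles if gene in p.copy_calls]
        altered = [e for e in events if e != "neutral"]
        if not altered:
            shared[gene] = "neutral"
            continue
        if len(altered) < len(events):
            divergent.append(gene)
            continue
        directions = {"gain" if e in ("gain", "amplification") else "loss" for e in altered}
        if len(directions) > 1:
            divergent.append(gene)
            continue
        # shared category = the least severe event every metastasis reaches
        shared[gene] = min(altered, key=lambda e: _SEVERITY[e])

    mut_shared: dict[str, str] = {}
    bi_shared: dict[str, bool] = {}
    for gene in genes:
        muts = {p.mutation_classes.get(gene) for p in profiles}
        if len(muts) == 1 and None not in muts:
            mut_shared[gene] = next(iter(muts))  # type: ignore[arg-type]
        bis = {p.biallelic.get(gene, False) for p in profiles}
        if bis == {True}:
            bi_shared[gene] = True

    return PatientSharedProfile(
        patient_id=profiles[0].patient_id,
        n_metastases=len(profiles),
        shared_events=shared,
        divergent_genes=tuple(divergent),
        shared_mutations=mut_shared,
        shared_biallelic=bi_shared,
    )


def genotype_flags(
    profile: PatientSharedProfile,
    genes: Sequence[str] = DEFAULT_GENES,
    conjunctions: Sequence[tuple[str, ...]] = (("RB1", "TP53"), ("PTEN", "RB1")),
) -> dict[str, bool]:
    """Boolean altered/unaltered flags used by the association battery.

    A gene is 'altered' when its shared copy-number event is non-neutral
    or a shared mutation class / biallelic-loss annotation is present.
    Conjunction flags (e.g. RB1&TP53) require every member altered.
    """
    known = set(profile.shared_events) | set(profile.shared_mutations) | set(
        profile.shared_biallelic
    )
    flags: dict[str, bool] = {}
    for gene in genes:
        if gene not in known and gene not in DEFAULT_GENES:
            raise ValueError(f"unknown gene requested: {gene}")
        altered = (
            profile.shared_events.get(gene, "neutral") != "neutral"
            or gene in profile.shared_mutations
            or profile.shared_biallelic.get(gene, False)
        )
        flags[f"{gene}_altered"] = altered
        flags[f"{gene}_biallelic"] = profile.shared_biallelic.get(gene, False)
    for combo in conjunctions:
        flags["&".join(combo) + "_altered"] = all(
            flags.get(f"{g}_altered", False) for g in combo
        )
    return flags
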