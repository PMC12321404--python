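"""Readers, writers, run configuration, and the end-to-end pipeline.

Input tables are comma-separated UTF-8 with a header row, "." decimal and
empty string for missing. The long IHC format has one row per core x
marker (columns patient_id, site, block_id, core_id, marker, value), with
Ki-67 carried as marker "Ki67" on the percent scale; a wide per-core
format (one column per marker) is also accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .associations import (
    kw_test,
    median_diff_ci,
    ne_site_model,
    pairwise_mwu_holm,
)
from .genomics import (
    GeneCopyCall,
    MetastasisGenomicProfile,
    genotype_flags,
    shared_alterations,
)
from .heterogeneity import (
    bootstrap_mean_ci,
    dichotomize_hi,
    ki67_intratumoral_hi,
    ki67_patient_hi,
    subtype_hi,
)
from .ihc import (
    OPTIONAL_MARKERS,
    REQUIRED_MARKERS,
    SUBTYPE_LABELS,
    CoreMeasurement,
    TumorSample,
    classify_sample,
    normalize_site,
)

logger = logging.getLogger("methet")

LONG_COLUMNS = ("patient_id", "site", "block_id", "core_id", "marker", "value")
KI67_MARKER = "Ki67"


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    hscore_table: str = ""
    genomic_table: str = ""
    clinical_table: str = ""
    out_dir: str = "results"
    unit: str = "sample"              # sample | core
    combine_method: str = "max"       # max | mean
    hscore_threshold: float = 20.0
    ki67_threshold: float = 20.0
    hi_cutoff: float = 50.0
    cell_score_threshold: float = 0.1
    n_boot: int = 1000
    seed: int = 17
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.unit not in ("sample", "core"):
            raise ValueError("unit must be 'sample' or 'core'")
        if not (0 < self.hscore_threshold <= 200):
            raise ValueError("hscore_threshold out of range")
        if not (0 < self.ki67_threshold < 100):
            raise ValueError("ki67_threshold out of range")
        if not (0 <= self.hi_cutoff <= 100):
            raise ValueError("hi_cutoff out of range")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Hash of the analytic configuration (output/logging excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_hscore_table(path_or_df) -> list[CoreMeasurement]:
    """Read per-core IHC measurements from a long or wide CSV.

    Validates H-score and Ki-67 ranges with row-numbered messages,
    rejects duplicate (patient, block, core, marker) rows, and maps
    unknown anatomic sites to "other" with a warning.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"patient_id": str, "block_id": str,
                                            "core_id": str})
    if set(LONG_COLUMNS).issubset(df.columns):
        return _cores_from_long(df)
    wide_required = {"patient_id", "site", "block_id", "core_id"}
    if wide_required.issubset(df.columns):
        return _cores_from_wide(df)
    raise ValueError(
        "IHC table must have columns "
        f"{LONG_COLUMNS} (long) or {sorted(wide_required)} + marker columns (wide)"
    )


def _cores_from_long(df: pd.DataFrame) -> list[CoreMeasurement]:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    key = ["patient_id", "block_id", "core_id", "marker"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"duplicate (patient, block, core, marker) rows at lines {rows}")
    for i, row in df.iterrows():
        v = float(row["value"])
        line = i + 2
        if row["marker"] == KI67_MARKER:
            if not (0 <= v <= 100):
                raise ValueError(f"line {line}: Ki-67 {v} outside [0, 100]")
        elif not (0 <= v <= 200):
            raise ValueError(f"line {line}: H-score {v} outside [0, 200] for "
                             f"marker {row['marker']}")
    cores: list[CoreMeasurement] = []
    grouped = df.groupby(["patient_id", "block_id", "core_id"], sort=True)
    for (pid, block, core), g in grouped:
        sites = {normalize_site(s) for s in g["site"].unique()}
        if len(sites) > 1:
            raise ValueError(f"core {pid}/{block}/{core} spans multiple sites")
        hscores = {
            r["marker"]: float(r["value"])
            for _, r in g.iterrows()
            if r["marker"] != KI67_MARKER
        }
        ki = g.loc[g["marker"] == KI67_MARKER, "value"]
        cores.append(CoreMeasurement(
            patient_id=str(pid), site=sites.pop(), block_id=str(block),
            core_id=str(core), hscores=hscores,
            ki67=float(ki.iloc[0]) if len(ki) else None,
        ))
    return cores


def _cores_from_wide(df: pd.DataFrame) -> list[CoreMeasurement]:
    id_cols = {"patient_id", "site", "block_id", "core_id"}
    marker_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(id_vars=sorted(id_cols), value_vars=marker_cols,
                   var_name="marker", value_name="value").dropna(subset=["value"])
    return _cores_from_long(long.reset_index(drop=True))


def read_genomic_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"patient_id": str, "metastasis_id": str})
    required = {"patient_id", "metastasis_id", "gene", "pacn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genomic table missing column(s): {sorted(missing)}")
    if (df["pacn"] < 0).any():
        bad = df.index[df["pacn"] < 0][0] + 2
        raise ValueError(f"line {bad}: negative PACN")
    if "mutation_class" not in df.columns:
        df["mutation_class"] = ""
    if "biallelic" not in df.columns:
        df["biallelic"] = False
    df["mutation_class"] = df["mutation_class"].fillna("")
    df["biallelic"] = df["biallelic"].fillna(False).astype(bool)
    return df


def read_clinical_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    return pd.read_csv(path_or_df, dtype={"patient_id": str})


# ---------------------------------------------------------------------------
# pipeline stages on in-memory tables
# ---------------------------------------------------------------------------


def cores_to_units(
    cores: Sequence[CoreMeasurement], unit: str = "sample", combine_method: str = "max"
) -> list[TumorSample]:
    """Group cores into classification units: tissue blocks or single cores."""
    if unit == "core":
        return [
            TumorSample(
                patient_id=c.patient_id, site=c.site,
                block_id=f"{c.block_id}:{c.core_id}",
                cores=(c,), combined_hscores=dict(c.hscores), combined_ki67=c.ki67,
            )
            for c in cores
        ]
    groups: dict[tuple, list[CoreMeasurement]] = {}
    for c in cores:
        groups.setdefault((c.patient_id, c.site, c.block_id), []).append(c)
    return [TumorSample.from_cores(g, method=combine_method) for g in
            (groups[k] for k in sorted(groups))]


def build_sample_table(samples: Sequence[TumorSample],
                       hscore_threshold: float = 20.0) -> pd.DataFrame:
    rows = []
    for s in samples:
        call = classify_sample(s.combined_hscores, threshold=hscore_threshold)
        row = {
            "patient_id": s.patient_id,
            "site": s.site,
            "block_id": s.block_id,
            "n_cores": len(s.cores),
            "ar_positive": call.ar_positive,
            "ne_positive": call.ne_positive,
            "subtype": call.label,
            "ki67": s.combined_ki67,
        }
        for m in REQUIRED_MARKERS + OPTIONAL_MARKERS:
            if m in s.combined_hscores:
                row[m] = s.combined_hscores[m]
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["patient_id", "block_id"]).reset_index(drop=True)


def build_patient_summary(
    sample_table: pd.DataFrame,
    cores: Sequence[CoreMeasurement] | None = None,
    ki67_threshold: float = 20.0,
    hi_cutoff: float = 50.0,
) -> pd.DataFrame:
    """Per-patient subtype counts, dominant subtype, and the three HIs."""
    from .ihc import summarize_labels

    rows = []
    ki67_blocks: dict[str, dict[str, list[float]]] = {}
    if cores is not None:
        for c in cores:
            if c.ki67 is not None:
                ki67_blocks.setdefault(c.patient_id, {}).setdefault(
                    c.block_id, []).append(c.ki67)

    for pid, g in sample_table.groupby("patient_id", sort=True):
        summary = summarize_labels(pid, g["subtype"].tolist())
        hi = subtype_hi(summary.counts)
        ki = g["ki67"].dropna().tolist()
        ki_hi = ki67_patient_hi(ki, threshold=ki67_threshold) if len(ki) >= 2 else None
        row = {
            "patient_id": pid,
            "n_samples": summary.n_samples,
            "dominant": summary.dominant,
            "dominant_tied": summary.dominant_tied,
            "heterogeneous": summary.heterogeneous,
            "hi": hi.value,
            "hi_defined": hi.defined,
            "hi_category": dichotomize_hi(hi.value, cutoff=hi_cutoff),
            "ki67_hi": ki_hi.value if ki_hi and ki_hi.defined else None,
        }
        for lab in SUBTYPE_LABELS:
            row[f"frac {lab}"] = summary.fractions[lab]
        if pid in ki67_blocks:
            it = ki67_intratumoral_hi(ki67_blocks[pid], threshold=ki67_threshold)
            row["ki67_intratumoral_hi"] = it.value if it.defined else None
        else:
            row["ki67_intratumoral_hi"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def build_genomic_profiles(genomic_df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Patient x gene shared-event matrix plus per-patient boolean flags."""
    event_rows = []
    flags_by_patient: dict[str, dict[str, bool]] = {}
    for pid, g in genomic_df.groupby("patient_id", sort=True):
        profiles = []
        for mid, gm in g.groupby("metastasis_id", sort=True):
            calls = {r["gene"]: GeneCopyCall.from_pacn(r["gene"], r["pacn"])
                     for _, r in gm.iterrows()}
            muts = {r["gene"]: r["mutation_class"] for _, r in gm.iterrows()
                    if r["mutation_class"]}
            bi = {r["gene"]: bool(r["biallelic"]) for _, r in gm.iterrows()}
            profiles.append(MetastasisGenomicProfile(
                patient_id=pid, metastasis_id=mid, copy_calls=calls,
                mutation_classes=muts, biallelic=bi,
            ))
        shared = shared_alterations(profiles)
        flags_by_patient[pid] = genotype_flags(shared)
        for gene, event in shared.shared_events.items():
            event_rows.append({
                "patient_id": pid, "gene": gene, "event": event,
                "divergent": gene in shared.divergent_genes,
                "mutation_class": shared.shared_mutations.get(gene, ""),
                "biallelic": shared.shared_biallelic.get(gene, False),
            })
        for gene in shared.divergent_genes:
            event_rows.append({
                "patient_id": pid, "gene": gene, "event": "divergent",
                "divergent": True, "mutation_class": "", "biallelic": False,
            })
    return pd.DataFrame(event_rows), flags_by_patient


def analyze_cohort(
    hscore_input,
    genomic_input=None,
    clinical_input=None,
    unit: str = "sample",
    combine_method: str = "max",
    hscore_threshold: float = 20.0,
    ki67_threshold: float = 20.0,
    hi_cutoff: float = 50.0,
    n_boot: int = 1000,
    seed: int = 17,
) -> dict:
    """Run subtyping -> summaries -> HIs -> genomics -> associations.

    Accepts file paths or DataFrames; returns a dict of result tables and
    summary objects.
    """
    cores = read_hscore_table(hscore_input)
    units = cores_to_units(cores, unit=unit, combine_method=combine_method)
    sample_table = build_sample_table(units, hscore_threshold=hscore_threshold)
    patient_summary = build_patient_summary(
        sample_table, cores=cores, ki67_threshold=ki67_threshold, hi_cutoff=hi_cutoff
    )

    results: dict = {
        "sample_table": sample_table,
        "patient_summary": patient_summary,
        "cores": cores,
    }

    # cohort-level bootstrap summaries
    hi_vals = patient_summary.loc[patient_summary.hi_defined, "hi"].tolist()
    if len(hi_vals) >= 2:
        results["hi_bootstrap"] = bootstrap_mean_ci(hi_vals, n_boot=n_boot, seed=seed)
    ki_vals = patient_summary["ki67_hi"].dropna().tolist()
    if len(ki_vals) >= 2:
        results["ki67_hi_bootstrap"] = bootstrap_mean_ci(
            ki_vals, n_boot=n_boot, seed=seed + 1)
    it_vals = patient_summary["ki67_intratumoral_hi"].dropna().tolist()
    if len(it_vals) >= 2:
        results["ki67_intratumoral_hi_bootstrap"] = bootstrap_mean_ci(
            it_vals, n_boot=n_boot, seed=seed + 2)

    # associations: NE odds by site; HI by dominant subtype
    comparisons = []
    try:
        results["ne_site_model"] = ne_site_model(sample_table)
    except ValueError as exc:
        logger.warning("NE-by-site model skipped: %s", exc)
    hi_by_dom = {
        dom: g.loc[g.hi_defined, "hi"].tolist()
        for dom, g in patient_summary.groupby("dominant")
    }
    hi_by_dom = {k: v for k, v in hi_by_dom.items() if len(v) >= 2}
    if len(hi_by_dom) >= 2:
        comparisons.append(kw_test(hi_by_dom))
        comparisons.extend(pairwise_mwu_holm(hi_by_dom))
    ki67_by_subtype = {
        sub: g["ki67"].dropna().tolist()
        for sub, g in sample_table.groupby("subtype")
    }
    ki67_by_subtype = {k: v for k, v in ki67_by_subtype.items() if len(v) >= 2}
    if len(ki67_by_subtype) >= 2:
        comparisons.append(kw_test(ki67_by_subtype))
        comparisons.extend(pairwise_mwu_holm(ki67_by_subtype))

    # genomics + HI-by-genotype associations
    if genomic_input is not None:
        genomic_df = read_genomic_table(genomic_input)
        if len(genomic_df):
            event_matrix, flags = build_genomic_profiles(genomic_df)
            results["genomic_events"] = event_matrix
            results["genomic_flags"] = flags
            hi_def = patient_summary.loc[patient_summary.hi_defined]
            for flag_name in ("AR_altered", "PTEN_altered", "RB1_altered",
                              "TP53_altered"):
                alt, wt = [], []
                for _, row in hi_def.iterrows():
                    f = flags.get(row.patient_id)
                    if f is None:
                        continue
                    (alt if f.get(flag_name) else wt).append(row.hi)
                if len(alt) >= 2 and len(wt) >= 2:
                    cmp = median_diff_ci(alt, wt)
                    comparisons.append(ComparisonRow(flag_name, cmp))

    results["comparisons"] = comparisons

    if clinical_input is not None:
        results["clinical_table"] = read_clinical_table(clinical_input)

    results["comutation_matrix"] = build_comutation_matrix(results)
    return results


class ComparisonRow:
    """A ComparisonResult tagged with the genotype flag it compares."""

    def __init__(self, flag: str, result):
        self.flag = flag
        self.result = result

    def __repr__(self) -> str:  # pragma: no cover
        return f"ComparisonRow({self.flag}, {self.result})"


def build_comutation_matrix(results: dict) -> dict:
    """Per-patient JSON record mirroring a comutation-plot layout:
    dominant subtype, subtype fractions, HI, and shared genomic events."""
    patients = {}
    events = results.get("genomic_events")
    by_patient_events: dict[str, dict] = {}
    if events is not None and len(events):
        for pid, g in events.groupby("patient_id"):
            by_patient_events[pid] = dict(zip(g["gene"], g["event"]))
    for _, row in results["patient_summary"].iterrows():
        patients[row.patient_id] = {
            "dominant": row.dominant,
            "fractions": {lab: row[f"frac {lab}"] for lab in SUBTYPE_LABELS},
            "hi": None if row.hi is None or (isinstance(row.hi, float)
                                             and np.isnan(row.hi)) else row.hi,
            "genomic_events": by_patient_events.get(row.patient_id),
        }
    return patients


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline from files and write outputs plus a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results = analyze_cohort(
        config.hscore_table,
        genomic_input=config.genomic_table or None,
        clinical_input=config.clinical_table or None,
        unit=config.unit,
        combine_method=config.combine_method,
        hscore_threshold=config.hscore_threshold,
        ki67_threshold=config.ki67_threshold,
        hi_cutoff=config.hi_cutoff,
        n_boot=config.n_boot,
        seed=config.seed,
    )

    files = {}
    results["sample_table"].to_csv(out / "samples.csv", index=False)
    files["samples.csv"] = _file_hash(out / "samples.csv")
    results["patient_summary"].to_csv(out / "patients.csv", index=False)
    files["patients.csv"] = _file_hash(out / "patients.csv")
    if "genomic_events" in results:
        results["genomic_events"].to_csv(out / "genomic_events.csv", index=False)
        files["genomic_events.csv"] = _file_hash(out / "genomic_events.csv")

    cohort = cohort_summary(results)
    (out / "cohort_summary.json").write_text(json.dumps(cohort, indent=2, sort_keys=True))
    files["cohort_summary.json"] = _file_hash(out / "cohort_summary.json")

    (out / "comutation.json").write_text(
        json.dumps(results["comutation_matrix"], indent=2, sort_keys=True))
    files["comutation.json"] = _file_hash(out / "comutation.json")

    import methet

    manifest = {
        "package_version": methet.__version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def cohort_summary(results: dict) -> dict:
    """JSON-serializable cohort-level summary of a pipeline run."""
    ps = results["patient_summary"]
    summary: dict = {
        "n_patients": int(ps.patient_id.nunique()),
        "n_samples": int(results["sample_table"].shape[0]),
        "dominant_counts": ps["dominant"].value_counts().to_dict(),
        "n_heterogeneous": int(ps["heterogeneous"].sum()),
        "n_homogeneous": int((~ps["heterogeneous"]).sum()),
    }
    for key in ("hi_bootstrap", "ki67_hi_bootstrap", "ki67_intratumoral_hi_bootstrap"):
        if key in results:
            b = results[key]
            summary[key] = {
                "mean": b.point_estimate, "ci_low": b.ci_low, "ci_high": b.ci_high,
                "n_boot": b.n_boot,
            }
    if "ne_site_model" in results:
        m = results["ne_site_model"]
        summary["ne_site_odds_ratios"] = {
            s: {"or": m.odds_ratios[s], "ci": list(m.or_ci[s]), "p": m.p_values[s]}
            for s in m.odds_ratios
        }
        summary["ne_site_model_sigma"] = m.sigma
    return summary


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
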