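"""End-to-end orchestration: generate -> derive views -> test -> IBR-T ->
NMDS -> ANOVA, seeded throughout, with plain-text artifacts and a manifest.

Every stage reads its inputs from the output directory and writes its own
CSV/JSON artifact there, so a single stage can be rerun from cached inputs
and reproduce its artifact bit-exactly. The manifest records the seed, the
full configuration, the package version and a SHA-256 checksum per artifact;
identical configuration and seed give identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import FactorialModel
from .data import (
    BIOMARKERS,
    read_biomarker_table,
    read_viability_table,
    summarize_groups,
    write_biomarker_table,
    write_viability_table,
)
from .ibrt import IBRT
from .nonparametric import kruskal_dunn_table
from .ordination import NMDS, euclidean_distances, impute_missing, zscore
from .simulate import EffectConfig, ViabilityConfig, generate_study, generate_viability

logger = logging.getLogger("ibrtox.pipeline")

ALL_STAGES = ("generate", "summarize", "test", "ibrt", "nmds", "anova")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; everything is echoed into the manifest."""

    seed: int = 0
    outdir: str = "ibrtox-out"
    #: Generator settings (used by the ``generate`` stage).
    n_per_cell: int = 7
    cv: float = 0.25
    dose_slope: float = 0.21
    day_gain: float = 1.5
    #: Analysis settings.
    adjustment: str = "none"
    viability_assay: str = "NR"
    impute_components: int = 2
    impute_tol: float = 1e-6
    nmds_starts: int = 100
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def build_feature_matrix(bio: pd.DataFrame, via: pd.DataFrame) -> pd.DataFrame:
    """Samples x variables view for ordination.

    One row per animal x biological matrix; enzyme columns (SOD, GPx, GST,
    MDA) are observed for the three solid tissues, viability columns (NR,
    TB) for hemolymph and hepatopancreas. Cells outside a matrix's assay
    panel are missing and are left to the imputation step, mirroring a
    dataset in which no compartment carries every variable.
    """
    wide = bio.pivot_table(
        index=["subject_id", "tissue", "treatment", "day"],
        columns="biomarker",
        values="value",
        observed=True,
    ).reset_index()
    wide = wide.rename(columns={"tissue": "Matrix", "treatment": "Treatment", "day": "Day"})
    via_wide = via.pivot_table(
        index=["subject_id", "compartment", "treatment", "day"],
        columns="assay",
        values="percent_viable",
        observed=True,
    ).reset_index()
    via_wide = via_wide.rename(
        columns={"compartment": "Matrix", "treatment": "Treatment", "day": "Day"}
    )
    merged = wide.merge(via_wide, on=["subject_id", "Matrix", "Treatment", "Day"], how="outer")
    cols = ["subject_id", "Matrix", "Treatment", "Day"] + [
        c for c in list(BIOMARKERS) + ["NR", "TB"] if c in merged.columns
    ]
    return (
        merged[cols]
        .sort_values(["Matrix", "Day", "Treatment", "subject_id"])
        .reset_index(drop=True)
    )


def build_model_table(
    bio: pd.DataFrame, via: pd.DataFrame, viability_assay: str = "NR"
) -> pd.DataFrame:
    """Long table for the factorial model, z-scored per biomarker level.

    Viability enters as one extra Biomarker level (the chosen assay), so the
    Matrix factor spans all four compartments including hemolymph.
    """
    enz = bio.rename(
        columns={"tissue": "Matrix", "treatment": "Treatment", "day": "Day", "biomarker": "Biomarker"}
    )[["Treatment", "Day", "Matrix", "Biomarker", "value"]]
    v = via[via["assay"] == viability_assay].rename(
        columns={"compartment": "Matrix", "treatment": "Treatment", "day": "Day"}
    )
    v = v.assign(Biomarker="viability", value=v["percent_viable"])[
        ["Treatment", "Day", "Matrix", "Biomarker", "value"]
    ]
    table = pd.concat([enz, v], ignore_index=True)
    table["Day"] = table["Day"].astype(str)

    def _z(col: pd.Series) -> pd.Series:
        return (col - col.mean()) / col.std(ddof=1)

    table["value"] = table.groupby("Biomarker", observed=True)["value"].transform(_z)
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages and return the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages is not None else tuple(config.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")

    if "generate" in stages:
        logger.info("[generate] synthesising study (seed=%d)", config.seed)
        eff = EffectConfig(
            cv=config.cv,
            dose_slope=config.dose_slope,
            day_gain=config.day_gain,
            n_per_cell=config.n_per_cell,
            seed=config.seed,
        )
        bio = generate_study(eff)
        via = generate_viability(ViabilityConfig(n_per_cell=config.n_per_cell), config.seed)
        write_biomarker_table(bio, out / "biomarkers.csv")
        write_viability_table(via, out / "viability.csv")

    def _bio():
        return read_biomarker_table(out / "biomarkers.csv")

    def _via():
        return read_viability_table(out / "viability.csv")

    if "summarize" in stages:
        logger.info("[summarize] group summaries")
        summarize_groups(_bio()).to_csv(out / "group_summaries.csv", index=False)

    if "test" in stages:
        logger.info("[test] Kruskal-Wallis + Dunn per stratum")
        omnibus, pairwise = kruskal_dunn_table(_bio(), adjustment=config.adjustment)
        omnibus.to_csv(out / "kruskal_wallis.csv", index=False)
        pairwise.to_csv(out / "dunn_pairwise.csv", index=False)
        v_omni, v_pair = kruskal_dunn_table(
            _via(),
            value="percent_viable",
            within=("compartment", "assay", "day"),
            adjustment=config.adjustment,
        )
        v_omni.to_csv(out / "viability_kruskal_wallis.csv", index=False)
        v_pair.to_csv(out / "viability_dunn_pairwise.csv", index=False)

    if "ibrt" in stages:
        logger.info("[ibrt] threshold-based integrative biomarker response")
        results = IBRT(_bio()).fit()
        results.scores.to_csv(out / "ibrt_scores.csv", index=False)
        results.details.to_csv(out / "ibrt_details.csv", index=False)
        (out / "ibrt_settings.json").write_text(json.dumps(results.settings, indent=2) + "\n")

    if "nmds" in stages:
        logger.info("[nmds] ordination (%d starts)", config.nmds_starts)
        features = build_feature_matrix(_bio(), _via())
        meta = features[["subject_id", "Matrix", "Treatment", "Day"]]
        x = features.drop(columns=["subject_id", "Matrix", "Treatment", "Day"])
        z = zscore(x)
        imputed = impute_missing(z, n_components=config.impute_components, tol=config.impute_tol)
        dist = euclidean_distances(imputed)
        res = NMDS(dist, n_starts=config.nmds_starts, seed=config.seed).fit()
        coords = meta.copy()
        coords["NMDS1"] = res.coordinates[:, 0]
        coords["NMDS2"] = res.coordinates[:, 1]
        coords.to_csv(out / "nmds_coordinates.csv", index=False)
        (out / "nmds.json").write_text(
            json.dumps(
                {
                    "stress": res.stress,
                    "classification": res.classification,
                    "n_starts": res.n_starts,
                    "best_start": res.best_start,
                    "converged": bool(res.converged),
                },
                indent=2,
            )
            + "\n"
        )

    if "anova" in stages:
        logger.info("[anova] factorial model, Type III")
        table = build_model_table(_bio(), _via(), config.viability_assay)
        fit = FactorialModel.from_dataframe(table).fit()
        fit.anova_table.to_csv(out / "anova.csv", index=False)
        (out / "anova.json").write_text(
            fit.anova_table.to_json(orient="records", indent=2) + "\n"
        )

    artifacts = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.asdict(),
        "stages_run": list(stages),
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("[done] %d artifacts in %s", len(artifacts), out)
    return manifest
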