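"""End-to-end pipeline: configuration, validation, stage sequencing and a
consolidated run report.

Stages run in method order: simulate (synthetic dataset + ground truth) ->
sip-quant (labeled proportions/abundances per gene) -> partition (guild
potentials and percentage contributions) -> classify (per-ASV metabolic
calls) -> stats (ANOVA + Duncan letters on replicate potentials).  All
randomness flows from one root seed, split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import classify as _classify
from . import partition as _partition
from . import sipquant as _sipquant
from . import stats as _stats
from . import synthetic as _synthetic

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "validate_inputs"]

log = logging.getLogger("nitrisip")

__version__ = "0.1.0"

STAGES = ("simulate", "sip_quant", "partition", "classify", "stats")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    preset: Literal["CK", "WI1", "WI2"] = "CK"
    seed: int = 0
    out_dir: str = "nitrisip_out"
    stages: tuple[str, ...] = STAGES

    # gradient / slurry protocol parameters
    n_fractions: int = 15
    density_min: float = 1.690
    density_max: float = 1.760
    peak_sd: float = 0.006
    noise_cv: float = 0.05
    n_replicates: int = 3
    measurement_sd: float = 0.02
    soil_water_volume_L: float = Field(0.005, description="V of Np = R*(0.1+V)/m*24")
    soil_dry_mass_kg: float = Field(0.0095, description="m of Np = R*(0.1+V)/m*24")

    # analysis options
    window_mode: Literal["fixed", "adaptive"] = "adaptive"
    heavy_threshold: float = 1.725
    estimator: Literal["normalized_excess", "raw_excess"] = "normalized_excess"
    alpha: float = 0.05
    correction: Literal["none", "BH"] = "none"
    qc_r2: float = 0.9
    ace_baseline: bool = False
    class_mapping: Literal["mechanistic", "literal"] = "mechanistic"

    def gradient_protocol(self) -> _synthetic.GradientProtocol:
        return _synthetic.GradientProtocol(
            n_fractions=self.n_fractions, density_min=self.density_min,
            density_max=self.density_max, peak_sd=self.peak_sd,
            noise_cv=self.noise_cv, n_replicates=self.n_replicates,
        )

    def slurry_protocol(self) -> _synthetic.SlurryProtocol:
        return _synthetic.SlurryProtocol(
            soil_water_volume=self.soil_water_volume_L,
            soil_dry_mass=self.soil_dry_mass_kg,
            measurement_sd=self.measurement_sd,
            n_replicates=self.n_replicates,
        )


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and sanity checks for the pipeline input tables.

    Returns a machine-readable list of issues, each naming the file, the
    column and (where applicable) the offending row number.
    """
    schemas = {
        "gradients": {"gene", "isotope", "replicate", "fraction", "density_g_ml", "copies"},
        "slurry": {"soil", "substrate", "inhibitor_combo", "analyte", "replicate",
                   "time_h", "conc_mgN_L"},
        "totals": {"gene", "treatment", "copies_per_g"},
        "asv_counts": {"asv_id", "context", "isotope", "replicate", "count"},
    }
    issues: list[dict] = []
    for name, path in paths.items():
        path = Path(path)
        if name not in schemas:
            issues.append({"file": str(path), "issue": f"unknown table kind {name!r}"})
            continue
        if not path.exists():
            issues.append({"file": str(path), "issue": "file not found"})
            continue
        df = pd.read_csv(path, sep="\t")
        missing = schemas[name] - set(df.columns)
        if missing:
            issues.append({"file": str(path), "issue": "missing columns",
                           "columns": sorted(missing)})
            continue
        if name == "gradients":
            neg = df.index[df["copies"] < 0]
            for row in neg:
                issues.append({"file": str(path), "issue": "negative copies",
                               "column": "copies", "row": int(row)})
        if name == "slurry":
            keys = ["soil", "substrate", "inhibitor_combo", "analyte", "replicate"]
            for key, g in df.groupby(keys):
                t = g.sort_index()["time_h"].to_numpy()
                dup = np.flatnonzero(np.diff(np.sort(t)) == 0)
                if dup.size:
                    row = int(g.index[np.argsort(t)[dup[0] + 1]])
                    issues.append({"file": str(path), "issue": "duplicated time point",
                                   "column": "time_h", "row": row,
                                   "series": "/".join(map(str, key))})
            counts = df.groupby(keys[:4])["replicate"].nunique()
            if counts.nunique() > 1:
                issues.append({"file": str(path), "issue": "unbalanced replicates"})
        if name == "asv_counts":
            if (df["count"] < 0).any():
                row = int(df.index[df["count"] < 0][0])
                issues.append({"file": str(path), "issue": "negative count",
                               "column": "count", "row": row})
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the consolidated report.

    Returns the run report as a dict (also written to ``report.json`` in the
    output directory).  A stage failure raises :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(STAGES, root.spawn(len(STAGES)))
    }
    report: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    scenario = None

    if "simulate" in config.stages:
        log.info("stage simulate: preset %s seed %d", config.preset, config.seed)
        try:
            scenario = _synthetic.make_scenario(
                config.preset, seed=stage_seeds["simulate"],
                gradient_protocol=config.gradient_protocol(),
                slurry_protocol=config.slurry_protocol(),
                out_dir=out,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", str(e)) from e
        report["stages"]["simulate"] = {"status": "ok", "preset": config.preset}

    def _read(name: str) -> pd.DataFrame:
        path = out / f"{name}.tsv"
        if not path.exists():
            raise StageError(name, f"required input {path} not found")
        return pd.read_csv(path, sep="\t")

    issues = validate_inputs(
        {k: out / f"{k}.tsv" for k in ("gradients", "slurry", "totals", "asv_counts")
         if (out / f"{k}.tsv").exists()}
    )
    if issues:
        report["warnings"].extend(issues)

    if "sip_quant" in config.stages:
        log.info("stage sip_quant")
        try:
            pairs = _sipquant.pairs_from_table(_read("gradients"))
            totals = _read("totals").set_index("gene")["copies_per_g"]
            rows = []
            for gene, pair in pairs.items():
                est = _sipquant.quantify_pair(
                    pair, float(totals.get(gene, 0.0)),
                    window_mode=config.window_mode, threshold=config.heavy_threshold,
                    estimator=config.estimator, seed=stage_seeds["sip_quant"],
                )
                if not est.heavy_window:
                    report["warnings"].append(
                        {"stage": "sip_quant", "gene": gene, "issue": "empty heavy window"}
                    )
                rows.append(
                    {"gene": gene, "treatment": config.preset,
                     "window": ",".join(map(str, est.heavy_window)),
                     "p_hat": est.p_hat, "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "labeled_abundance": est.labeled_abundance, "p_value": est.p_value}
                )
            est_df = pd.DataFrame(rows)
            est_df.to_csv(out / "label_estimates.tsv", sep="\t", index=False)
            _atomic_write(out / "label_estimates.json",
                          est_df.to_json(orient="records", indent=2))
            report["stages"]["sip_quant"] = {
                "status": "ok",
                "estimates": est_df.to_dict(orient="records"),
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("sip_quant", str(e)) from e

    if "partition" in config.stages:
        log.info("stage partition")
        try:
            results, potentials = _partition.partition_from_table(
                _read("slurry"), V=config.soil_water_volume_L,
                m=config.soil_dry_mass_kg, qc_r2=config.qc_r2,
                ace_baseline=config.ace_baseline,
            )
            if not results:
                raise KeyError("no soil x substrate block carries the five required assays")
            potentials.to_csv(out / "potentials.tsv", sep="\t", index=False)
            for r in results:
                for fl in r.flags:
                    report["warnings"].append(
                        {"stage": "partition", "soil": r.soil, "issue": fl}
                    )
            part_rows = [dataclasses.asdict(r) for r in results]
            part_df = pd.json_normalize(part_rows)
            part_df.to_csv(out / "partition.tsv", sep="\t", index=False)
            _atomic_write(out / "partition.json", json.dumps(part_rows, indent=2))
            interactions = _partition.interaction_report(results)
            report["stages"]["partition"] = {
                "status": "ok",
                "results": part_rows,
                "interactions": interactions.to_dict(orient="records"),
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("partition", str(e)) from e

    if "classify" in config.stages:
        log.info("stage classify")
        try:
            counts = _read("asv_counts")
            ctx = {c: df.drop(columns="context") for c, df in counts.groupby("context")}
            calls, class_counts = _classify.classify_table(
                ctx["no_inhibitor"], ctx["ace"], alpha=config.alpha,
                correction=config.correction, mapping=config.class_mapping,
            )
            calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
            calls_df.to_csv(out / "metabolic_calls.tsv", sep="\t", index=False)
            _atomic_write(out / "class_counts.json", json.dumps(class_counts, indent=2))
            report["stages"]["classify"] = {"status": "ok", "class_counts": class_counts}
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", str(e)) from e

    if "stats" in config.stages:
        log.info("stage stats")
        try:
            potentials = pd.read_csv(out / "potentials.tsv", sep="\t")
            keyed = potentials[
                potentials.apply(
                    lambda r: (frozenset(str(r["inhibitor_combo"]).split("+"))
                               if r["inhibitor_combo"] != "none" else frozenset(),
                               r["analyte"]) in _partition.ASSAY_ROLES,
                    axis=1,
                )
            ]
            keyed = keyed.assign(
                role=keyed.apply(
                    lambda r: _partition.ASSAY_ROLES[
                        (frozenset(str(r["inhibitor_combo"]).split("+"))
                         if r["inhibitor_combo"] != "none" else frozenset(),
                         r["analyte"])
                    ],
                    axis=1,
                )
            )
            grouped = _stats.GroupedMeasurements.from_dict(
                {role: g["Np"].tolist() for role, g in keyed.groupby("role")}
            )
            anova = _stats.one_way_anova(grouped)
            letters = _stats.duncan_mrt(grouped, alpha=config.alpha, anova=anova)
            stats_df = pd.DataFrame(
                {"group": letters.labels, "mean_Np": letters.means,
                 "letters": letters.letters}
            )
            stats_df["F"] = anova.f_statistic
            stats_df["p"] = anova.p_value
            stats_df.to_csv(out / "stats_report.tsv", sep="\t", index=False)
            report["stages"]["stats"] = {
                "status": "ok",
                "anova": {"F": anova.f_statistic, "df": [anova.df_between, anova.df_within],
                          "p": anova.p_value},
                "letters": letters.as_dict(),
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("stats", str(e)) from e

    if scenario is not None:
        report["truth"] = json.loads(scenario.truth.to_json())
    _atomic_write(out / "report.json", json.dumps(report, indent=2, sort_keys=True))
    return report
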