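"""Pipeline orchestration: run configuration, stage wiring and manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import amplicon_profiles as ap
from . import differential_shifts as ds
from . import glv_core as glv
from . import process_chemistry as chem
from . import synthetic_data as synth

log = logging.getLogger("digestor")

STAGES = ("simulate", "chem", "profile", "diff", "glv")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated parameters for an end-to-end run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    counts: Path | None = None  # external inputs; generated when absent
    metadata: Path | None = None
    schedule: Path | None = None
    alpha: float = 0.05
    ridge: float = 1e-3
    epsilon: float = 0.0
    top_n: int = 10
    rank: str = "genus"
    n_taxa: int = 24
    depth: int = 50_000
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.ridge < 0 or self.epsilon < 0:
            raise ConfigError("ridge and epsilon must be >= 0")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        for name in ("counts", "metadata", "schedule"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "out_dir" not in doc:
            raise ConfigError("config must set out_dir")
        kwargs: dict[str, Any] = {"out_dir": Path(doc.pop("out_dir"))}
        for key in ("seed", "alpha", "ridge", "epsilon", "top_n", "rank",
                    "n_taxa", "depth", "noise_cv"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        if "stages" in doc:
            kwargs["stages"] = tuple(doc.pop("stages"))
        for key in ("counts", "metadata", "schedule"):
            if key in doc and doc[key] is not None:
                kwargs[key] = Path(doc.pop(key))
            else:
                doc.pop(key, None)
        if doc:
            raise ConfigError(f"unknown config keys: {sorted(doc)}")
        return cls(**kwargs)

    def param_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in sorted(vars(self).items())
            if k != "out_dir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_schedule(path: str | Path) -> tuple[chem.ReactorConfig, dict[str, list[chem.FeedingEvent]]]:
    """Read a reactor + per-condition feeding schedule YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    reactor = chem.ReactorConfig(**doc["reactor"])
    conditions = {
        cond: [chem.FeedingEvent(**ev) for ev in events]
        for cond, events in doc.get("conditions", {}).items()
    }
    return reactor, conditions


def chemistry_report(
    reactor: chem.ReactorConfig,
    conditions: dict[str, list[chem.FeedingEvent]],
) -> pd.DataFrame:
    """Tidy per-condition weekly OLR table plus retention time."""
    rows = []
    hrt = chem.retention_time_report(reactor)
    for cond, events in conditions.items():
        for rep in chem.weekly_loading_rates(events):
            rows.append(
                {
                    "condition": cond,
                    "week": rep.week + 1,
                    "olr_gvs_per_l_d": rep.olr,
                    "olr_2dp": rep.olr_2dp,
                    "retention_time_d": hrt["days"],
                    "retention_time_2dp": hrt["days_2dp"],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    Stage order: simulate (fixture generation) -> chem || profile -> diff ->
    glv. A stage failure is recorded in the manifest and stops dependent
    stages; the manifest is always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
    }
    ok = True

    counts_path, metadata_path, schedule_path = config.counts, config.metadata, config.schedule

    if "simulate" in config.stages:
        try:
            design = synth.StudyDesign(n_taxa=config.n_taxa, depth=config.depth)
            paths = synth.generate_study(
                out / "fixtures", design=design, seed=config.seed, noise_cv=config.noise_cv
            )
            counts_path = counts_path or paths["counts"]
            metadata_path = metadata_path or paths["metadata"]
            schedule_path = schedule_path or paths["schedule"]
            manifest["stages"]["simulate"] = {
                "status": "ok",
                "outputs": [str(p.relative_to(out)) for p in paths.values()],
            }
        except Exception as exc:  # noqa: BLE001 - recorded in manifest
            log.exception("simulate stage failed")
            manifest["stages"]["simulate"] = {"status": "failed", "error": str(exc)}
            ok = False

    if "chem" in config.stages and ok:
        try:
            if schedule_path is None:
                raise ConfigError("chem stage needs a schedule (enable simulate or pass one)")
            reactor, conditions = load_schedule(schedule_path)
            report = chemistry_report(reactor, conditions)
            report.to_csv(out / "chemistry.tsv", sep="\t", index=False)
            manifest["stages"]["chem"] = {"status": "ok", "outputs": ["chemistry.tsv"]}
        except Exception as exc:  # noqa: BLE001
            log.exception("chem stage failed")
            manifest["stages"]["chem"] = {"status": "failed", "error": str(exc)}
            ok = False

    table = profiles = None
    if "profile" in config.stages and ok:
        try:
            if counts_path is None or metadata_path is None:
                raise ConfigError("profile stage needs counts and metadata tables")
            table = ap.AbundanceTable.from_tsv(counts_path, metadata_path)
            genus = ap.aggregate_rank(table, config.rank)
            rel = ap.relative_abundance(genus)
            rel.proportions.to_csv(out / "relative_abundance.tsv", sep="\t")
            profiles = {
                cond: ap.RelativeProfile(
                    proportions=rel.proportions.loc[table.metadata["condition"] == cond],
                    lineages=rel.lineages,
                )
                for cond in table.metadata["condition"].unique()
            }
            kept = ap.intersect_top(profiles, config.top_n)
            (out / "top_taxa.json").write_text(json.dumps({"kept": kept}, indent=1))
            bc = ap.bray_curtis(rel)
            bc.to_csv(out / "bray_curtis.tsv", sep="\t")
            ord_res = ap.ordinate(bc)
            ord_res.coordinates.to_csv(out / "ordination.tsv", sep="\t")
            manifest["stages"]["profile"] = {
                "status": "ok",
                "n_samples": len(rel.sample_ids),
                "kept_taxa": kept,
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("profile stage failed")
            manifest["stages"]["profile"] = {"status": "failed", "error": str(exc)}
            ok = False

    if "diff" in config.stages and ok:
        try:
            if table is None:
                raise ConfigError("diff stage needs the profile stage")
            meta = table.metadata
            stressors = [c for c in meta["condition"].unique() if c != "control"]
            days = sorted(meta["day"].unique())
            venn_records = []
            for day in days[1:]:  # day 0 predates any treatment
                shiftsets = {}
                for cond in stressors:
                    results = ds.fallback_da_test(table, cond, "control", day=int(day))
                    ds.write_da_table(results, out / f"da_{cond}_d{day}.tsv")
                    shiftsets[cond] = ds.significant_shifts(results, alpha=config.alpha)
                if len(shiftsets) == 3:
                    summary = ds.venn_classify(shiftsets)
                    for rec in summary.to_records():
                        venn_records.append({"day": int(day), **rec})
            pd.DataFrame(venn_records).to_csv(out / "venn_summary.tsv", sep="\t", index=False)
            (out / "venn_summary.json").write_text(json.dumps(venn_records, indent=1))
            manifest["stages"]["diff"] = {"status": "ok", "n_regions": len(venn_records)}
        except Exception as exc:  # noqa: BLE001
            log.exception("diff stage failed")
            manifest["stages"]["diff"] = {"status": "failed", "error": str(exc)}
            ok = False

    if "glv" in config.stages and ok:
        try:
            if table is None or profiles is None:
                raise ConfigError("glv stage needs the profile stage")
            kept = ap.intersect_top(profiles, config.top_n)
            if len(kept) < 2:
                raise RuntimeError("fewer than 2 taxa shared across all top-N lists")
            summaries, sign_matrices = [], {}
            meta = table.metadata
            rel_full = ap.relative_abundance(ap.aggregate_rank(table, config.rank))
            for cond in meta["condition"].unique():
                sub = rel_full.proportions.loc[meta["condition"] == cond, kept]
                sub_meta = meta.loc[sub.index]
                mean_by_day = sub.groupby(sub_meta["day"]).mean().sort_index()
                traj = glv.Trajectory.from_observations(
                    mean_by_day.index.to_numpy(float), mean_by_day.to_numpy(), kept
                )
                model, diag = glv.infer(traj, ridge=config.ridge)
                model.to_json(out / f"glv_{cond}.json")
                signs = glv.classify_signs(model, epsilon=config.epsilon)
                sign_matrices[cond] = signs
                summary = glv.count_interactions(signs, label=cond)
                summaries.append(
                    {
                        "condition": cond,
                        "positive": summary.positive,
                        "negative": summary.negative,
                        "neutral": summary.neutral,
                        "mean_r2": float(np.mean(diag.r_squared)),
                    }
                )
            if "control" in sign_matrices:
                ctrl = sign_matrices["control"]
                for row in summaries:
                    cond = row["condition"]
                    if cond == "control":
                        continue
                    row["shared_with_control"] = glv.shared_interactions(ctrl, sign_matrices[cond])
                    row["unique"] = glv.unique_interactions(
                        sign_matrices[cond],
                        [m for c, m in sign_matrices.items() if c != cond],
                    )
            pd.DataFrame(summaries).to_csv(out / "interaction_summary.tsv", sep="\t", index=False)
            for cond, signs in sign_matrices.items():
                pd.DataFrame(signs.signs, index=kept, columns=kept).to_csv(
                    out / f"signs_{cond}.tsv", sep="\t"
                )
            manifest["stages"]["glv"] = {"status": "ok", "taxa": kept}
        except Exception as exc:  # noqa: BLE001
            log.exception("glv stage failed")
            manifest["stages"]["glv"] = {"status": "failed", "error": str(exc)}
            ok = False

    manifest["status"] = "ok" if ok else "failed"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
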