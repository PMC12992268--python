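"""End-to-end pipeline: simulate/load -> hemoglobin -> responses -> features
-> selection -> classification, with a serializable run configuration.

Every run directory contains ``features.csv``, ``selection.csv``,
``reports/*.json``, optional ``figures/``, a ``manifest.json`` naming each
artifact, and a log; every output records the configuration hash so any
artifact is traceable to the exact run settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tdio
from .classify import TABLE_FEATURE_SETS, ClassifierSpec, boundary_grid, fit_predict
from .features import build_feature_table, sample_features, select_features
from .physics import (
    GatedSeries,
    HbOSeries,
    estimate_mua_from_pair,
    gate_records,
    mbll_delta_hbo,
    rhbo_series,
)
from .responses import ChannelQuality, QualityThresholds, reject_channels, summarize_rejections
from .synthetic import Cohort, CohortSpec, SyntheticSample, generate_cohort

log = logging.getLogger("tdnirs.pipeline")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    alpha: float = 0.05
    classifiers: list[ClassifierSpec] = field(default_factory=list)
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "features": True,
            "select": True,
            "classify": True,
            "figures": False,
        }
    )
    save_tpsf: bool = False

    def __post_init__(self) -> None:
        if not self.classifiers:
            self.classifiers = [
                ClassifierSpec(model="lda", features=TABLE_FEATURE_SETS["F7_F8"], cv_seed=self.seed),
                ClassifierSpec(model="lda", features=TABLE_FEATURE_SETS["F7_F12"], cv_seed=self.seed),
                ClassifierSpec(model="gaussian_nb", features=TABLE_FEATURE_SETS["5D"], cv_seed=self.seed),
                ClassifierSpec(model="linear_svm", features=TABLE_FEATURE_SETS["F7_F8"], cv_seed=self.seed),
            ]

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return clean(dataclasses.asdict(self))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .physics import ExtinctionTable, GateSet, OpticalProperties
        from .protocol import TaskProtocol
        from .synthetic import (
            FamilyEffect,
            GroupEffect,
            GroupEffectSpec,
            ResponseClassParams,
            VariabilitySpec,
        )

        d = dict(d)

        def build_family(fd: dict) -> FamilyEffect:
            return FamilyEffect(
                activated=ResponseClassParams(**fd["activated"]),
                suppressive=ResponseClassParams(**fd["suppressive"]),
                suppressive_fraction=fd["suppressive_fraction"],
            )

        cohort_d = dict(d.get("cohort", {}))
        if cohort_d:
            if "protocol" in cohort_d:
                cohort_d["protocol"] = TaskProtocol(**cohort_d["protocol"])
            if "optical" in cohort_d:
                cohort_d["optical"] = OpticalProperties(**cohort_d["optical"])
            if "gate_set" in cohort_d:
                gates = tuple(tuple(g) for g in cohort_d["gate_set"]["gates"])
                cohort_d["gate_set"] = GateSet(gates=gates)
            if "extinction" in cohort_d:
                e = cohort_d["extinction"]
                cohort_d["extinction"] = ExtinctionTable(
                    wavelengths_nm=tuple(e["wavelengths_nm"]),
                    eps_hbo=tuple(e["eps_hbo"]),
                    eps_hbr=tuple(e["eps_hbr"]),
                )
            if "effects" in cohort_d:
                e = cohort_d["effects"]
                cohort_d["effects"] = GroupEffectSpec(
                    hc=GroupEffect(
                        rhbo1=build_family(e["hc"]["rhbo1"]),
                        rhbo2=build_family(e["hc"]["rhbo2"]),
                    ),
                    mdd=GroupEffect(
                        rhbo1=build_family(e["mdd"]["rhbo1"]),
                        rhbo2=build_family(e["mdd"]["rhbo2"]),
                    ),
                    variability=VariabilitySpec(**e.get("variability", {})),
                )
            d["cohort"] = CohortSpec(**cohort_d)
        if "thresholds" in d:
            d["thresholds"] = QualityThresholds(**d["thresholds"])
        if "classifiers" in d:
            d["classifiers"] = [
                ClassifierSpec(**{**c, "features": tuple(c["features"])})
                for c in d["classifiers"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def hbo_from_tpsf(
    sample: SyntheticSample,
    spec: CohortSpec,
    thresholds: QualityThresholds | None = None,
) -> tuple[GatedSeries, ChannelQuality, dict[str, HbOSeries]]:
    """Physics path: gate a TPSF recording and derive all five families.

    Channel rejection is decided once at the photon-count level; the
    resulting quality applies to every derived family of the recording.
    """
    protocol = spec.protocol
    baseline = protocol.baseline_window()
    gated = gate_records(sample.tpsf, spec.gate_set, protocol=protocol)
    quality = reject_channels(gated, thresholds, protocol)
    hbo: dict[str, HbOSeries] = {}
    delta = mbll_delta_hbo(
        gated, baseline, spec.extinction, n_tissue=spec.optical.n_tissue, protocol=protocol
    )
    for series in delta:
        hbo[f"dHbO{series.index}"] = series
    for pair in (1, 2):
        mua = estimate_mua_from_pair(gated, pair, spec.optical)
        hbo[f"RHbO{pair}"] = rhbo_series(mua, baseline, spec.extinction, protocol=protocol)
    return gated, quality, hbo


def cohort_feature_table(
    cohort: Cohort, thresholds: QualityThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table for either rendering mode of a synthetic cohort."""
    protocol = cohort.spec.protocol
    if cohort.spec.mode == "hbo_direct":
        return build_feature_table(cohort.samples, protocol, thresholds)
    rows, qrows = [], []
    for s in cohort.samples:
        _, quality, hbo = hbo_from_tpsf(s, cohort.spec, thresholds)
        feats, qr = sample_features(hbo, protocol, thresholds, quality=quality)
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "group": s.group,
                "session": s.session,
                **feats,
            }
        )
        for q in qr:
            qrows.append({"sample_id": s.sample_id, **q})
    return pd.DataFrame(rows), pd.DataFrame(qrows)


def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path.

    Deterministic given the config (the cohort seed is overridden by the
    run seed): running twice with the same config produces byte-identical
    tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config_hash": cfg_hash, "artifacts": [], "timings_s": {}}
    try:
        log.info("run start, config hash %s", cfg_hash)
        config.to_yaml(out / "config.yaml")
        manifest["artifacts"].append("config.yaml")

        cohort = None
        features = None
        if config.stages.get("simulate", True):
            t0 = time.perf_counter()
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = generate_cohort(spec)
            tdio.write_csv(
                pd.DataFrame(
                    [
                        {
                            "sample_id": s.sample_id,
                            "subject_id": s.subject_id,
                            "group": s.group,
                            "session": s.session,
                        }
                        for s in cohort.samples
                    ]
                ),
                out / "samples.csv",
                cfg_hash,
            )
            tdio.write_csv(cohort.truth, out / "truth.csv", cfg_hash)
            manifest["artifacts"] += ["samples.csv", "truth.csv"]
            if config.save_tpsf and spec.mode == "tpsf":
                tpsf_dir = out / "tpsf"
                tpsf_dir.mkdir(exist_ok=True)
                for s in cohort.samples:
                    tdio.write_tpsf_h5(tpsf_dir / f"{s.sample_id}.h5", s.tpsf)
                manifest["artifacts"].append("tpsf/")
            manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)
            log.info("simulated %d samples", len(cohort.samples))

        if config.stages.get("features", True):
            if cohort is None:
                raise ValueError("feature stage requires the simulate stage (or cached inputs)")
            t0 = time.perf_counter()
            features, quality = cohort_feature_table(cohort, config.thresholds)
            tdio.write_csv(features, out / "features.csv", cfg_hash)
            tdio.write_csv(quality, out / "quality.csv", cfg_hash)
            manifest["artifacts"] += ["features.csv", "quality.csv"]
            manifest["timings_s"]["features"] = round(time.perf_counter() - t0, 3)
            rej = summarize_rejections(
                quality.groupby("sample_id")["n_rejected"].max().to_numpy(),
                config.cohort.n_channels,
            )
            manifest["rejection_summary"] = rej
            log.info(
                "features for %d samples; mean rejected %.2f/%d channels (%d%%)",
                len(features),
                rej["mean_rejected"],
                rej["n_channels"],
                rej["percent_rejected"],
            )

        if config.stages.get("select", True) and features is not None:
            t0 = time.perf_counter()
            report = select_features(features, alpha=config.alpha)
            tdio.write_csv(report.reset_index(), out / "selection.csv", cfg_hash)
            manifest["artifacts"].append("selection.csv")
            manifest["timings_s"]["select"] = round(time.perf_counter() - t0, 3)
            log.info("selected %d features at alpha=%.2f", int(report["selected"].sum()), config.alpha)

        if config.stages.get("classify", True) and features is not None:
            t0 = time.perf_counter()
            reports_dir = out / "reports"
            for cspec in config.classifiers:
                rep = fit_predict(cspec, features)
                name = f"{cspec.model}_{'_'.join(cspec.features)}"
                tdio.write_report_json(rep.to_dict(), reports_dir / f"{name}.json", cfg_hash)
                manifest["artifacts"].append(f"reports/{name}.json")
                if config.stages.get("figures", False) and len(cspec.features) == 2:
                    _plot_boundary(rep, features, out / "figures" / f"{name}.png")
                    manifest["artifacts"].append(f"figures/{name}.png")
            manifest["timings_s"]["classify"] = round(time.perf_counter() - t0, 3)
            log.info("classified with %d model specs", len(config.classifiers))

        tdio.write_report_json(manifest, out / "manifest.json")
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _plot_boundary(report, features: pd.DataFrame, path: Path) -> None:
    """Scatter plot of the two groups with the fitted decision boundary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = boundary_grid(report)
    path.parent.mkdir(parents=True, exist_ok=True)
    fx, fy = report.spec.features
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(grid.x, grid.y, grid.labels, levels=[-0.5, 0.5, 1.5], alpha=0.15, colors=["tab:blue", "tab:red"])
    ax.contour(grid.x, grid.y, grid.labels, levels=[0.5], colors="k", linewidths=1.0)
    kept = features.dropna(subset=[fx, fy])
    for grp, color in (("HC", "tab:blue"), ("MDD", "tab:red")):
        sub = kept[kept["group"] == grp]
        ax.scatter(sub[fx], sub[fy], s=18, c=color, label=grp, edgecolors="none")
    ax.set_xlabel(fx)
    ax.set_ylabel(fy)
    ax.legend(frameon=False)
    ax.set_title(f"{report.spec.model}: {fx} vs {fy}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
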