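"""Config-driven end-to-end runner: simulate/read -> extract -> subset search.

Produces a reproducible report bundle (TSV/JSON outputs plus a manifest with
checksums) and optional figures.
"""

from __future__ import annotations

import dataclasses
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
from .erp import ErpParams, FeatureExtraction, extract_features
from .essearch import ElectrodeReport, run_electrode
from .synth import (
    ANALYSIS_ELECTRODES,
    ComponentParams,
    GenerativeConfig,
    read_dataset,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed for one end-to-end run."""

    mode: str = "synthetic"  # or "real-data"
    data_dir: str | None = None
    out_dir: str = "results/run"
    seed: int = 0
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    erp: ErpParams = field(default_factory=ErpParams)
    electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES
    top_k: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real-data":
            if self.data_dir is None or not Path(self.data_dir).exists():
                raise ValueError("real-data mode requires an existing data_dir")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        gen = raw.pop("generative", {})
        if isinstance(gen, dict):
            gen = dict(gen)
            comps = gen.pop("component_params", None)
            for key in ("trait_bounds", "condition_ratio", "fixation_ms"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            for key in ("latency_slopes", "amplitude_slopes"):
                if key in gen:
                    gen[key] = {_parse_key(k): v for k, v in gen[key].items()}
            cfg = GenerativeConfig(**gen)
            if comps is not None:
                cfg.component_params = {
                    _parse_key(k): ComponentParams(**v) for k, v in comps.items()
                }
            gen = cfg
        erp = raw.pop("erp", {})
        if isinstance(erp, dict):
            erp = dict(erp)
            for key in ("band_hz", "epoch_window_ms", "baseline_window_ms"):
                if key in erp and erp[key] is not None:
                    erp[key] = tuple(erp[key])
            if "peak_windows" in erp:
                erp["peak_windows"] = {
                    k: tuple(v) for k, v in erp["peak_windows"].items()
                }
            if "electrodes" in erp:
                erp["electrodes"] = tuple(erp["electrodes"])
            erp = ErpParams(**erp)
        if "electrodes" in raw:
            raw["electrodes"] = tuple(raw["electrodes"])
        return cls(generative=gen, erp=erp, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        def encode(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    ("/".join(k) if isinstance(k, tuple) else k): encode(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return encode(self)


def _parse_key(key: str) -> tuple[str, str, str]:
    parts = tuple(key.split("/"))
    if len(parts) != 3:
        raise ValueError(f"expected 'component/condition/electrode' key, got {key!r}")
    return parts  # type: ignore[return-value]


@dataclass
class RunResult:
    config: RunConfig
    extraction: FeatureExtraction
    reports: dict[str, ElectrodeReport]
    out_dir: Path
    files: list[Path]


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "complete": False,
    }

    try:
        stage = "data"
        if config.mode == "synthetic":
            recordings, participants = simulate_dataset(config.generative, config.seed)
        else:
            recordings, participants = read_dataset(config.data_dir)
        logger.info("stage %s: %d participants", stage, len(participants))

        stage = "erp"
        extraction = extract_features(recordings, participants, config.erp)
        for elec, table in extraction.feature_tables.items():
            files.append(_write_tsv(table, out / f"features_{elec}.tsv"))
        (out / "exclusions.json").write_text(
            json.dumps(extraction.exclusions, indent=2)
        )
        files.append(out / "exclusions.json")
        for elec in config.electrodes:
            cols: dict[str, np.ndarray] = {}
            for cond in ("AW", "RW", "ST"):
                wf = extraction.grand_averages.get((cond, elec))
                if wf is None:
                    continue
                cols["time_ms"] = wf.times_ms
                cols[f"{cond}_mean"] = wf.mean
                cols[f"{cond}_se"] = wf.se
            if cols:
                files.append(
                    _write_tsv(pd.DataFrame(cols), out / f"grand_average_{elec}.tsv")
                )
        logger.info(
            "stage %s: retained %s, %d exclusion record(s)",
            stage,
            {e: len(t) for e, t in extraction.feature_tables.items()},
            len(extraction.exclusions),
        )

        stage = "essearch"
        reports: dict[str, ElectrodeReport] = {}
        for elec in config.electrodes:
            report = run_electrode(
                extraction.feature_tables[elec], elec, top_k=config.top_k
            )
            reports[elec] = report
            files.append(_write_tsv(report.table, out / f"cve_table_{elec}.tsv"))
            files.append(
                _write_tsv(report.diagram.to_frame(), out / f"weight_diagram_{elec}.tsv")
            )
            (out / f"weight_diagram_{elec}.json").write_text(report.diagram.to_json())
            files.append(out / f"weight_diagram_{elec}.json")
            freq = pd.DataFrame(
                {
                    "variable": report.diagram.names,
                    "count": report.diagram.selection_counts,
                }
            )
            files.append(_write_tsv(freq, out / f"selection_frequency_{elec}.tsv"))
            best = report.best_fit
            best_df = pd.DataFrame(
                {
                    "variable": best.names,
                    "B": best.coef,
                    "stderr": best.stderr,
                    "beta": best.betas,
                    "pvalue": best.pvalues,
                }
            )
            files.append(_write_tsv(best_df, out / f"best_model_{elec}.tsv"))
            logger.info(
                "stage %s/%s: %d models, best CVE %.4f",
                stage,
                elec,
                len(report.table),
                report.top_models["cve"].iloc[0],
            )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["files"] = {str(p.name): _sha256(p) for p in files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    manifest["complete"] = True
    manifest["files"] = {str(p.name): _sha256(p) for p in files}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    files.append(mpath)
    return RunResult(
        config=config,
        extraction=extraction,
        reports=reports,
        out_dir=out,
        files=files,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_figures(result: RunResult, fmt: str = "png") -> list[Path]:
    """Grand-average traces with SE shading plus weight-diagram heat maps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = result.out_dir
    paths: list[Path] = []
    colors = {"AW": "tab:red", "RW": "tab:blue", "ST": "tab:gray"}

    for elec in result.config.electrodes:
        fig, ax = plt.subplots(figsize=(6, 4))
        plotted = False
        for cond in ("AW", "RW", "ST"):
            wf = result.extraction.grand_averages.get((cond, elec))
            if wf is None:
                continue
            ax.plot(wf.times_ms, wf.mean, color=colors[cond], label=cond)
            se = np.nan_to_num(wf.se)
            ax.fill_between(
                wf.times_ms, wf.mean - se, wf.mean + se, color=colors[cond], alpha=0.25
            )
            plotted = True
        if not plotted:
            plt.close(fig)
            raise ValueError(f"no grand averages available for {elec}")
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time from onset (ms)")
        ax.set_ylabel("potential (uV)")
        ax.set_title(f"grand average, {elec}")
        ax.legend()
        p = out / f"grand_average_{elec}.{fmt}"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)

        diagram = result.reports[elec].diagram
        fig, (ax0, ax1) = plt.subplots(
            2, 1, figsize=(8, 5), sharex=True, height_ratios=[1, 2]
        )
        ax0.plot(np.arange(diagram.k), diagram.cves, "o-", ms=3)
        ax0.set_ylabel("CVE")
        vmax = np.nanmax(np.abs(diagram.betas)) or 1.0
        cmap = plt.get_cmap("coolwarm").copy()
        cmap.set_bad("white")
        im = ax1.imshow(
            np.ma.masked_invalid(diagram.betas.T),
            aspect="auto",
            cmap=cmap,
            vmin=-vmax,
            vmax=vmax,
            interpolation="nearest",
        )
        ax1.set_yticks(range(len(diagram.names)), diagram.names, fontsize=7)
        ax1.set_xlabel("models ranked by CVE")
        fig.colorbar(im, ax=ax1, label="standardized coefficient")
        fig.suptitle(f"weight diagram, {elec}")
        p = out / f"weight_diagram_{elec}.{fmt}"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
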