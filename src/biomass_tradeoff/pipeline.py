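"""End-to-end orchestration: simulate/read -> validate -> trade-off ->
allometry -> group statistics -> driver attribution, with plain-text
outputs (CSV/JSON), a run log and deterministic figures.

Each stage writes its own file and consumes only files/frames produced by
earlier stages, so any stage can be re-run standalone from the output
directory.  The JSON report records the config hash so runs are auditable.
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

from . import allometry as allom
from . import drivers as drv
from . import groupstats as gs
from . import tradeoff as to
from .data import ClassScheme, read_quadrats, write_quadrats
from .synthetic import GeneratorConfig, SurveyDesign, generate_survey

__all__ = ["RunConfig", "run_pipeline", "make_figures", "analysis_frame"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("biomass_tradeoff")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (an existing quadrat table) or ``generator``
    (synthesize one) must be set.  ``stages`` toggles the analysis stages;
    the simulate/validate stage always runs.  Every stochastic stage takes
    its seed from ``seeds``.
    """

    output_dir: str | Path = "run_output"
    input_csv: str | Path | None = None
    generator: GeneratorConfig | None = None
    class_edges: tuple[float, ...] = (400.0, 500.0, 600.0, 700.0)
    stages: tuple[str, ...] = ("tradeoff", "allometry", "groupstats", "drivers")
    seeds: dict = field(default_factory=lambda: {"generator": 0, "rf": 0, "mantel": 0})
    tradeoff_mode: str = "per-quadrat"
    rf_trees: int = 500
    mantel_perms: int = 999

    def resolved_generator(self) -> GeneratorConfig:
        gen = self.generator or GeneratorConfig(design=SurveyDesign(class_edges=self.class_edges))
        return gen.with_seed(int(self.seeds.get("generator", 0)))

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # where results land is not part of what they are
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analysis_frame(scored: pd.DataFrame) -> pd.DataFrame:
    """Variables entering the structural model: z-ready log-scale drivers.

    Biomass pools and SLA are log-transformed (right-skewed, multiplicative
    responses); precipitation and the trade-off enter untransformed.
    """
    return pd.DataFrame(
        {
            "map": scored["map_mm"].astype(float),
            "agb": np.log(scored["agb_gm2"].astype(float)),
            "bgb": np.log(scored["bgb_gm2"].astype(float)),
            "sla": np.log(scored["sla"].astype(float)),
            "richness": scored["richness"].astype(float),
            "tradeoff": scored["tradeoff"].astype(float),
        }
    )


def _stage_groupstats(table: pd.DataFrame) -> dict:
    out = {}
    groups = table["precip_class"].astype(str).to_numpy()
    for var in ("agb_gm2", "bgb_gm2", "total_gm2"):
        values = table[var].to_numpy(dtype=float)
        route = gs.choose_route(values, groups)
        comp = gs.compare_groups(values, groups, route=route, variable=var)
        out[var] = {
            "route": comp.route,
            "omnibus_stat": comp.omnibus_stat,
            "omnibus_p": comp.omnibus_p,
            "letters": comp.letters,
            "pairwise": comp.pairwise.to_dict(orient="records"),
        }
        smooth = gs.fit_smooth(table, "map_mm", var)
        out[var]["smooth"] = {
            "predictor": "map_mm",
            "edf": smooth.edf,
            "deviance_explained": smooth.deviance_explained,
        }
    return out


def _stage_drivers(scored: pd.DataFrame, config: RunConfig) -> dict:
    frame = analysis_frame(scored)
    screen = drv.correlation_screen(
        frame, target="tradeoff", columns=["tradeoff", "map", "agb", "bgb", "sla", "richness"]
    )
    # Mantel at site level: quadrat-level matrices are enormous and sites
    # are the climatic sampling unit.
    site = scored.groupby("site_id", observed=True).agg(
        tradeoff=("tradeoff", "mean"), map_mm=("map_mm", "first")
    )
    mantel = drv.mantel_test(
        drv.distance_matrix(site["tradeoff"].to_numpy()),
        drv.distance_matrix(site["map_mm"].to_numpy()),
        n_perm=config.mantel_perms,
        seed=int(config.seeds.get("mantel", 0)),
        names=("tradeoff", "map"),
    )
    importance = drv.rf_importance(
        scored,
        target="tradeoff",
        n_trees=config.rf_trees,
        seed=int(config.seeds.get("rf", 0)),
    )
    model = drv.fit_path_model(frame)
    fitstats = drv.model_fit_stats(model, frame)
    return {
        "correlations": {
            "r": screen.r.round(6).to_dict(),
            "p": screen.p.to_dict(),
        },
        "mantel": dataclasses.asdict(mantel),
        "rf_importance": [dataclasses.asdict(r) for r in importance],
        "sem": {
            "paths": [
                {"from": a, "to": b, "beta": beta, "p": p} for a, b, beta, p in model.paths
            ],
            "fisher_c": model.fisher_c,
            "fisher_df": model.fisher_df,
            "fisher_p": model.fisher_p,
            "indirect_effects": [
                {"chain": " -> ".join(chain), "beta_product": bp}
                for chain, bp in model.indirect_effects
            ],
            "r2": model.r2,
            "fit": dataclasses.asdict(fitstats),
        },
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Writes quadrats.csv, tradeoff.csv, tradeoff_classes.csv, allometry.csv,
    groupstats.json, drivers.json, report.json and run.log (depending on
    enabled stages).  Raises on the first failing stage, naming it.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "config_hash": config.config_hash(), "stages": {}}

    try:
        scheme = ClassScheme(edges=config.class_edges)
        if config.input_csv is not None:
            stage = "validate"
            table = read_quadrats(config.input_csv, scheme=scheme)
            log.info("validate: read %d quadrats from %s", len(table), config.input_csv)
        else:
            stage = "simulate"
            gen = config.resolved_generator()
            table = generate_survey(gen)
            log.info("simulate: generated %d quadrats (%d sites)", len(table), gen.design.n_sites)
        write_quadrats(table, outdir / "quadrats.csv")
        report["stages"]["input"] = {
            "rows": int(len(table)),
            "sites": int(table["site_id"].nunique()),
            "plots": int(table["plot_id"].nunique()),
            "class_counts": table["precip_class"].value_counts().to_dict(),
        }

        scored = None
        if "tradeoff" in config.stages or "drivers" in config.stages:
            stage = "tradeoff"
            scored = to.tradeoff_table(table, mode=config.tradeoff_mode)
            classes = to.class_summary(scored, scheme)
            if "tradeoff" in config.stages:
                scored.drop(columns=["precip_class"]).to_csv(outdir / "tradeoff.csv", index=False)
                classes.to_csv(outdir / "tradeoff_classes.csv", index=False)
                report["stages"]["tradeoff"] = {
                    "rows": int(len(scored)),
                    "mode": config.tradeoff_mode,
                    "class_means": {str(r.precip_class): float(r.mean_tradeoff) for r in classes.itertuples()},
                }
            log.info("tradeoff: scored %d quadrats (mode=%s)", len(scored), config.tradeoff_mode)

        if "allometry" in config.stages:
            stage = "allometry"
            fits = allom.fit_allometry_by_class(table)
            rows = []
            for f in fits:
                iso = allom.test_isometry(f, table)
                rows.append(
                    {
                        "precip_class": f.class_label,
                        "n": f.n,
                        "slope": f.slope,
                        "intercept": f.intercept,
                        "ci_lo": f.slope_ci[0],
                        "ci_hi": f.slope_ci[1],
                        "r2": f.r2,
                        "method": f.method,
                        "isometry_p": iso.p_value,
                        "verdict": iso.verdict,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "allometry.csv", index=False)
            report["stages"]["allometry"] = {"n_classes": len(rows), "verdicts": {r["precip_class"]: r["verdict"] for r in rows}}
            log.info("allometry: fitted %d classes", len(rows))

        if "groupstats" in config.stages:
            stage = "groupstats"
            gstats = _stage_groupstats(table)
            (outdir / "groupstats.json").write_text(json.dumps(gstats, indent=2, default=float))
            report["stages"]["groupstats"] = {v: gstats[v]["route"] for v in gstats}
            log.info("groupstats: %d variables compared", len(gstats))

        if "drivers" in config.stages:
            stage = "drivers"
            dstats = _stage_drivers(scored, config)
            (outdir / "drivers.json").write_text(json.dumps(dstats, indent=2, default=float))
            report["stages"]["drivers"] = {
                "rf_top": dstats["rf_importance"][0]["variable"],
                "fisher_p": dstats["sem"]["fisher_p"],
            }
            log.info("drivers: rf top predictor = %s", dstats["rf_importance"][0]["variable"])

        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        return outdir
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()


def make_figures(outdir: str | Path) -> list[Path]:
    """Render figures from a completed run bundle (reads only its CSVs/JSON).

    log-log AGB-BGB scatter with the 1:1 line, trade-off vs MAP with the
    zero line, the importance bar chart, and a path-coefficient table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    table = pd.read_csv(outdir / "quadrats.csv")
    made: list[Path] = []

    scored_path = outdir / "tradeoff.csv"
    if scored_path.exists():
        scored = pd.read_csv(scored_path)
        if scored.empty:
            raise ValueError("empty trade-off stage output")
        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        la, lb = np.log10(scored["agb_gm2"]), np.log10(scored["bgb_gm2"])
        axes[0].scatter(lb, la, s=8, alpha=0.5, c="tab:green")
        lims = [min(lb.min(), la.min()), max(lb.max(), la.max())]
        axes[0].plot(lims, lims, "r:", label="1:1")
        axes[0].set_xlabel("log10 BGB (g/m2)")
        axes[0].set_ylabel("log10 AGB (g/m2)")
        axes[0].legend()
        axes[1].scatter(scored["map_mm"], scored["tradeoff"], s=8, alpha=0.5, c="tab:blue")
        axes[1].axhline(0.0, color="r", ls=":")
        axes[1].set_xlabel("MAP (mm/y)")
        axes[1].set_ylabel("trade-off (+AGB / -BGB)")
        fig.tight_layout()
        path = figdir / "tradeoff.png"
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append(path)

    drivers_path = outdir / "drivers.json"
    if drivers_path.exists():
        dstats = json.loads(drivers_path.read_text())
        imp = pd.DataFrame(dstats["rf_importance"])
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.barh(imp["variable"][::-1], imp["pct_inc_mse"][::-1], color="tab:orange")
        ax.set_xlabel("%IncMSE")
        fig.tight_layout()
        path = figdir / "importance.png"
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append(path)

        paths_df = pd.DataFrame(dstats["sem"]["paths"])
        fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(paths_df)))
        ax.axis("off")
        cells = [[f"{r['from']} -> {r['to']}", f"{r['beta']:.3f}", f"{r['p']:.3g}"] for _, r in paths_df.iterrows()]
        ax.table(cellText=cells, colLabels=["path", "std beta", "p"], loc="center")
        path = figdir / "paths.png"
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append(path)

    if not made:
        raise ValueError("no stage outputs found to plot")
    return made
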