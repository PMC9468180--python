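"""Multi-scenario orchestration and publication-style tables.

Runs generate -> life table -> predation -> bootstrap -> projection for one
or more scenarios and renders "mean ± SE letter" comparison tables, with
compact-letter-display groups derived from pairwise paired bootstrap tests.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._core import as_arrays
from .bootstrap import bootstrap_cohort, bootstrap_se, paired_bootstrap_test
from .cohort import Cohort, read_cohort, write_cohort
from .lifetable import LifeTableModel
from .predation import PredationModel
from .projection import build_schedule, initial_vector, project
from .scenarios import ScenarioConfig, default_scenarios, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "render_table",
    "compact_letter_display",
]

log = logging.getLogger("agestage")

COMPARE_PARAMS = ("R0", "r", "lambda", "T", "F", "Od", "APOP", "TPOP", "C0", "Qp")
ROUND_RATES = {"r", "lambda", "Qp", "psi", "omega"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """What to run, for which scenarios, and where to write it."""

    outdir: Path
    scenarios: list[ScenarioConfig] = field(default_factory=default_scenarios)
    cohort_paths: list[Path] = field(default_factory=list)  # pre-recorded cohorts
    seed: int = 0
    B: int = 2000
    horizon: int = 90
    project_pairs: int = 10
    operations: tuple[str, ...] = ("generate", "lifetable", "predation",
                                   "bootstrap", "project", "report")
    round_days: int = 2
    round_rates: int = 4


def _metadata_header(config: RunConfig, extra: dict | None = None) -> str:
    meta = {"seed": config.seed, "B": config.B, "version": __version__}
    if extra:
        meta.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               extra: dict | None = None, written: list[Path] | None = None) -> None:
    text = _metadata_header(config, extra) + df.to_csv(index=False)
    path.write_text(text, encoding="utf-8")
    if written is not None:
        written.append(path)


def compact_letter_display(significant: np.ndarray, order: list[str]) -> dict[str, str]:
    """Letters from a pairwise significance matrix (insert-and-absorb).

    Starts from one group holding every scenario; each significant pair
    splits the groups that contain both members; groups absorbed by a
    superset are dropped.  Members sharing no group never share a letter.
    Ties are broken by scenario order.
    """
    k = len(order)
    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for g in list(groups):
                if i in g and j in g:
                    groups.remove(g)
                    groups.extend([g - {i}, g - {j}])
            # absorb: drop groups contained in another
            groups = [
                g for g in groups
                if g and not any(g < h for h in groups)
            ]
            # deduplicate while preserving insertion order
            seen: list[set[int]] = []
            for g in groups:
                if g not in seen:
                    seen.append(g)
            groups = seen
    groups.sort(key=lambda g: min(g))
    letters = {name: "" for name in order}
    for letter_idx, g in enumerate(groups):
        letter = chr(ord("a") + letter_idx)
        for i in sorted(g):
            letters[order[i]] += letter
    return letters


def render_table(
    results: pd.DataFrame,
    style: str = "text",
    round_days: int = 2,
    round_rates: int = 4,
) -> str:
    """Render a parameter-by-scenario table of "mean ± SE letter" cells.

    ``results`` must have columns [parameter, scenario, mean, se, letter].
    CSV and text renderings contain identical numbers; a missing SE renders
    as an em-dash with a footnote.
    """
    missing_se = False

    def cell(row) -> str:
        digits = round_rates if row.parameter in ROUND_RATES else round_days
        if not math.isfinite(row.mean):
            return "--"
        if row.se is None or not math.isfinite(row.se):
            nonlocal missing_se
            missing_se = True
            return f"{row.mean:.{digits}f} ± — {row.letter}".rstrip()
        return f"{row.mean:.{digits}f} ± {row.se:.{digits}f} {row.letter}".rstrip()

    table = results.assign(cell=[cell(r) for r in results.itertuples()])
    wide = table.pivot(index="parameter", columns="scenario", values="cell")
    wide = wide.reindex(results.parameter.unique())
    wide = wide[list(dict.fromkeys(results.scenario))]
    if style == "csv":
        out = wide.to_csv()
    else:
        out = wide.to_string()
    if missing_se:
        out += "\n(— : standard error unavailable; fewer than 2 defined replicates)"
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages for every scenario.

    Writes per-scenario parameter tables and (with >= 2 scenarios) a
    cross-scenario comparison table with significance letters.  Any stage
    error aborts with a stage-named message and removes partial outputs.
    Deterministic under a fixed seed and B.
    """
    t0 = time.time()
    config.outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict = {"scenarios": {}, "files": written}
    stage = "setup"
    try:
        cohorts: list[Cohort] = []
        stage = "generate"
        for path in config.cohort_paths:
            cohorts.append(read_cohort(path))
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(len(config.scenarios) + 1)
        if "generate" in config.operations and not config.cohort_paths:
            for cfg, child in zip(config.scenarios, children[:-1]):
                seed = int(child.generate_state(1)[0] % (2**31))
                cohort = generate_cohort(cfg, seed=seed)
                cohorts.append(cohort)
                path = config.outdir / f"cohort_{cfg.label}.csv"
                write_cohort(cohort, path, metadata={"seed": seed, "version": __version__})
                written.append(path)
                log.info("generated %s (n=%d)", cfg.label, cohort.n_01)

        results = {}
        for cohort in cohorts:
            label = cohort.label or "cohort"
            entry: dict = {}
            arrays = as_arrays(cohort)
            stage = f"lifetable[{label}]"
            lt = LifeTableModel(arrays)
            lt.label = label
            res = lt.fit()
            entry["lifetable"] = res
            stage = f"predation[{label}]"
            pred = PredationModel(arrays, lifetable=res).fit()
            entry["predation"] = pred
            if "bootstrap" in config.operations:
                stage = f"bootstrap[{label}]"
                label_key = int.from_bytes(
                    hashlib.sha256(label.encode()).digest()[:4], "little"
                )
                seed = int(
                    np.random.SeedSequence([config.seed, label_key])
                    .generate_state(1)[0] % (2**31)
                )
                dist = bootstrap_cohort(arrays, B=config.B, seed=seed)
                entry["bootstrap"] = dist
                se = {k: bootstrap_se(v) for k, v in dist.params.items()}
                res.params.se = se
                entry["se"] = se
            if "lifetable" in config.operations:
                long_df, par_df = res.to_frames()
                _write_csv(long_df, config.outdir / f"lifetable_{label}.csv",
                           config, {"label": label}, written)
                _write_csv(par_df, config.outdir / f"parameters_{label}.csv",
                           config, {"label": label}, written)
            if "predation" in config.operations:
                plong, ppar = pred.to_frames()
                _write_csv(plong, config.outdir / f"predation_{label}.csv",
                           config, {"label": label}, written)
                _write_csv(ppar, config.outdir / f"predation_parameters_{label}.csv",
                           config, {"label": label}, written)
            if "project" in config.operations:
                stage = f"project[{label}]"
                sched = build_schedule(arrays)
                init = initial_vector(sched, pairs=config.project_pairs)
                proj = project(sched, init, config.horizon)
                entry["projection"] = proj
                _write_csv(proj.stage_totals(), config.outdir / f"projection_{label}.csv",
                           config, {"label": label}, written)
            results[label] = entry
        bundle["scenarios"] = results

        if "report" in config.operations and len(cohorts) >= 2:
            stage = "report"
            labels = [c.label or f"cohort{i}" for i, c in enumerate(cohorts)]
            rows = []
            for param in COMPARE_PARAMS:
                sig = np.zeros((len(cohorts), len(cohorts)), dtype=bool)
                for i in range(len(cohorts)):
                    for j in range(i + 1, len(cohorts)):
                        seed = int(
                            np.random.SeedSequence(
                                [config.seed, COMPARE_PARAMS.index(param), i, j]
                            ).generate_state(1)[0] % (2**31)
                        )
                        test = paired_bootstrap_test(
                            cohorts[i], cohorts[j], param, B=config.B, seed=seed
                        )
                        sig[i, j] = sig[j, i] = test.significant
                letters = compact_letter_display(sig, labels)
                for label in labels:
                    entry = results[label]
                    res = entry["lifetable"]
                    vals = res.params.as_dict()
                    vals.update({"C0": entry["predation"].C0,
                                 "Qp": entry["predation"].Qp})
                    rows.append(
                        {
                            "parameter": param,
                            "scenario": label,
                            "mean": vals[param],
                            "se": entry.get("se", {}).get(param, math.nan),
                            "letter": letters[label],
                        }
                    )
            comparison = pd.DataFrame(rows)
            bundle["comparison"] = comparison
            text = render_table(comparison, "text",
                                config.round_days, config.round_rates)
            csv_text = render_table(comparison, "csv",
                                    config.round_days, config.round_rates)
            path = config.outdir / "comparison.txt"
            path.write_text(_metadata_header(config) + text + "\n", encoding="utf-8")
            written.append(path)
            path = config.outdir / "comparison.csv"
            path.write_text(_metadata_header(config) + csv_text, encoding="utf-8")
            written.append(path)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return bundle
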