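"""Summary statistics and results output.

The headline statistic is **relative plasticity**: the population mean of
the summed plastic allelic values — averaged within demes, across demes,
and across successful replicates — divided by the optimal reaction-norm
slope (optimum step / cue slope = 10 under the defaults).  A value of 1 is
a pure-plasticity outcome, 0 pure genetic differentiation; values above 1
(hyperplasticity) or below 0 are possible.  **Mean instability** is the
same triple average of the summed instability allelic values (the
genotypic developmental-noise sd), or of the realized pleiotropic sd when
instability has no loci of its own.  Among-replicate spread is reported as
a coefficient of variation in percent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .environment import GradientSpec
from .genetics import pleiotropic_sd
from .population import Population
from .simulation import ReplicateResult, SimConfig

__all__ = [
    "RunSummary",
    "relative_plasticity",
    "mean_instability",
    "among_run_cv",
    "summarize",
    "write_results",
    "series_frame",
]


@dataclass
class RunSummary:
    """Replicate-averaged outcome of one parameter combination."""

    overall_mean_plasticity: float | None
    relative_plasticity: float | None
    mean_instability: float | None
    among_run_cv_plasticity: float | None
    n_successful: int
    n_attempts: int
    mean_plasticity_per_deme: np.ndarray | None = None


def _deme_means(values: np.ndarray, demes: np.ndarray) -> np.ndarray:
    """Mean of ``values`` per occupied deme (occupied demes only)."""
    order = np.argsort(demes, kind="stable")
    uniq, start = np.unique(demes[order], return_index=True)
    return np.array(
        [values[order[s:e]].mean()
         for s, e in zip(start, np.append(start[1:], len(order)))]
    )


def relative_plasticity(
    populations: Sequence[Population], grad: GradientSpec
) -> float:
    """Cross-replicate relative plasticity from raw populations.

    Averages the summed plastic allelic values over individuals within
    each deme, over demes, then over replicates, and divides by the
    optimal slope.  The averaging order is immaterial when every replicate
    occupies the same demes with equal sizes.
    """
    if not populations:
        raise ValueError("need at least one successful replicate")
    run_means = []
    for pop in populations:
        if pop.plastic is None:
            raise ValueError("population has no plastic loci")
        run_means.append(
            _deme_means(pop.plastic.sum(axis=1), pop.deme).mean()
        )
    return float(np.mean(run_means)) / grad.optimal_slope


def mean_instability(
    populations: Sequence[Population],
    *,
    pleiotropy_strength: float | None = None,
) -> float:
    """Cross-replicate mean developmental-noise sd.

    Independent-loci mode averages the summed instability alleles; with
    ``pleiotropy_strength`` given, averages the realized pleiotropic sd
    (instability loci do not exist in that variant).
    """
    if not populations:
        raise ValueError("need at least one successful replicate")
    run_means = []
    for pop in populations:
        if pleiotropy_strength is not None:
            vals = np.asarray(
                pleiotropic_sd(pop.plastic, pleiotropy_strength)
            )
        else:
            if pop.instability is None:
                raise ValueError(
                    "population has no instability loci; "
                    "pass pleiotropy_strength for the pleiotropic variant"
                )
            vals = pop.instability.sum(axis=1)
        run_means.append(_deme_means(vals, pop.deme).mean())
    return float(np.mean(run_means))


def among_run_cv(run_means: Iterable[float]) -> float:
    """Coefficient of variation across replicate means, in percent.

    ``sd / |mean| * 100`` with the sample sd (ddof=1).  NaN when the mean
    is zero (undefined) — callers should report it as missing.
    """
    x = np.asarray(list(run_means), dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 successful replicates")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(np.std(x, ddof=1) / abs(m) * 100.0)


def summarize(results: Sequence[ReplicateResult], config: SimConfig) -> RunSummary:
    """Aggregate replicate results (successful attempts only)."""
    ok = [r for r in results if not r.extinct]
    n_ok, n_att = len(ok), len(results)
    if not ok:
        return RunSummary(None, None, None, None, 0, n_att)
    has_plastic = config.loci.has_plastic
    mp = rp = cv = None
    if has_plastic:
        means = [r.mean_plasticity for r in ok]
        mp = float(np.mean(means))
        rp = mp / config.grad.optimal_slope
        cv = among_run_cv(means) if n_ok >= 2 else None
    mi = None
    if config.loci.has_instability or config.loci.pleiotropic:
        mi = float(np.mean([r.mean_instability for r in ok]))
    return RunSummary(
        overall_mean_plasticity=mp,
        relative_plasticity=rp,
        mean_instability=mi,
        among_run_cv_plasticity=cv,
        n_successful=n_ok,
        n_attempts=n_att,
    )


def _replicate_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "attempt": r.attempt,
                "seed": r.seed,
                "extinct": r.extinct,
                "n_generations_run": r.n_generations_run,
                "mean_plasticity": r.mean_plasticity,
                "final_plasticity": r.final_plasticity,
                "relative_plasticity": r.relative_plasticity,
                "mean_instability": r.mean_instability,
                "final_instability": r.final_instability,
            }
        )
    return pd.DataFrame(rows)


def series_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Long-format per-generation time series of all recorded replicates."""
    frames = []
    for r in results:
        if r.series is None:
            continue
        f = pd.DataFrame(r.series)
        f.insert(0, "attempt", r.attempt)
        frames.append(f)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def write_results(
    results: Sequence[ReplicateResult],
    config: SimConfig,
    out_dir: str | Path,
    *,
    write_series: bool = False,
) -> dict[str, Path]:
    """Write a tidy replicate table, a JSON run manifest, and optionally
    the per-generation time series.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rep_path = out / "replicates.csv"
    _replicate_frame(results).to_csv(rep_path, index=False)
    paths["replicates"] = rep_path

    summary = summarize(results, config)
    manifest = {
        "config": config.to_dict(),
        "seeds": [r.seed for r in results],
        "summary": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in asdict(summary).items()
            if k != "mean_plasticity_per_deme"
        },
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = man_path

    if write_series:
        ser_path = out / "series.csv"
        series_frame(results).to_csv(ser_path, index=False)
        paths["series"] = ser_path
    return paths
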