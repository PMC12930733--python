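"""Monte-Carlo performance evaluation of the pooled estimates.

Per scenario x method x ECOG contrast the summaries follow the standard
simulation-study measures: absolute bias AB, relative bias RB (%),
mean-squared error MSE, coverage rate CR (%) of the 95% CI, average CI width
AW, and the Monte-Carlo standard error of the bias.  The per-replicate truth
is the Cox estimate of the complete sampled dataset before amputation, so RB
is taken against the mean complete-data estimate of the contrast.  Failed
replicates propagate as missing entries, never as zeros.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._design import MISSING
from .amputation import MECHANISMS

METRICS = ["AB", "RB", "MSE", "CR", "AW", "MCSE_bias"]


class PerformanceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def required_nsim(var_estimate: float, target_mcse: float) -> int:
    """Smallest replication count with MCSE(bias) = sqrt(var/n) <= target."""
    if var_estimate <= 0 or target_mcse <= 0:
        raise PerformanceError("variance and target MCSE must be positive")
    x = var_estimate / target_mcse**2
    n = math.ceil(x * (1.0 - 1e-12))   # guard against float noise at integers
    return max(n, 1)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design."""

    n: int
    proportion: float
    mechanism: str

    @property
    def scenario_id(self) -> str:
        return f"n{self.n}_p{int(round(100 * self.proportion))}_{self.mechanism}"


def scenario_grid(sizes, proportions, mechanisms) -> list:
    """Full factorial grid, deterministic order (size, proportion, mechanism)."""
    sizes, proportions, mechanisms = list(sizes), list(proportions), list(mechanisms)
    if not sizes or not proportions or not mechanisms:
        raise PerformanceError("every scenario factor must be non-empty")
    for mech in mechanisms:
        if mech not in MECHANISMS:
            raise PerformanceError(f"unknown mechanism {mech!r}")
    return [ScenarioSpec(n, p, mech) for n, p, mech
            in itertools.product(sizes, proportions, mechanisms)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise replicate records into performance rows.

    ``records`` is tidy with columns scenario, replicate, method, term,
    truth, estimate, ci_low, ci_high and a ``failed`` flag; rows are grouped
    by (scenario, method, term).  Failed or incomplete replicates are
    excluded with ``n_effective`` reporting the count that remained; a group
    with no usable replicates yields a row of missing values.
    """
    required = {"scenario", "method", "term", "truth", "estimate",
                "ci_low", "ci_high", "failed"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise PerformanceError(f"records lack columns {sorted(missing_cols)}")

    rows = []
    for (scenario, method, term), grp in records.groupby(
            ["scenario", "method", "term"], sort=True):
        ok = (~grp["failed"].astype(bool)
              & grp["truth"].notna() & grp["estimate"].notna())
        g = grp.loc[ok]
        n_eff = len(g)
        if n_eff == 0:
            rows.append(dict(scenario=scenario, method=method, term=term,
                             AB=np.nan, RB=np.nan, MSE=np.nan, CR=np.nan,
                             AW=np.nan, MCSE_bias=np.nan, n_effective=0))
            continue
        err = g["estimate"].to_numpy() - g["truth"].to_numpy()
        ab = err.mean()
        mean_truth = g["truth"].to_numpy().mean()
        rb = 100.0 * ab / mean_truth if mean_truth != 0 else np.nan
        mse = float((err**2).mean())
        covered = ((g["ci_low"].to_numpy() <= g["truth"].to_numpy())
                   & (g["truth"].to_numpy() <= g["ci_high"].to_numpy()))
        cr = 100.0 * covered.mean()
        aw = float((g["ci_high"].to_numpy() - g["ci_low"].to_numpy()).mean())
        mcse = float(np.sqrt(err.var(ddof=1) / n_eff)) if n_eff > 1 else np.nan
        rows.append(dict(scenario=scenario, method=method, term=term,
                         AB=float(ab), RB=float(rb), MSE=mse, CR=float(cr),
                         AW=aw, MCSE_bias=mcse, n_effective=n_eff))
    return pd.DataFrame(rows)


def flag_bias(summary: pd.DataFrame, threshold_pct: float = 10.0) -> pd.DataFrame:
    """Mark each summary cell acceptable iff |RB| <= threshold (boundary
    inclusive); missing RB stays unflagged (NA)."""
    out = summary.copy()
    rb = out["RB"]
    out["acceptable"] = pd.array(np.abs(rb) <= threshold_pct, dtype="boolean")
    out.loc[rb.isna(), "acceptable"] = pd.NA
    return out


def diagnose_imputations(result, observed) -> pd.DataFrame:
    """Per-dataset summary of imputed vs observed ECOG values.

    ``observed`` is the vector of observed (non-deleted) ECOG values.
    ``mean_diff = mean_imp - mean_obs``; ``range_flag`` is True iff any
    imputed value falls outside {0,...,4}.
    """
    obs = np.asarray(observed, dtype=float)
    obs = obs[obs != MISSING]
    stats_obs = {
        "mean_obs": obs.mean() if len(obs) else np.nan,
        "sd_obs": obs.std(ddof=1) if len(obs) > 1 else np.nan,
        "median_obs": np.median(obs) if len(obs) else np.nan,
    }
    rows = []
    mask = result.imputed_mask
    for d, ds in enumerate(result.datasets):
        imp = ds["ecog"].to_numpy()[mask].astype(float)
        if len(imp):
            row = dict(dataset=d, mean_imp=imp.mean(),
                       sd_imp=imp.std(ddof=1) if len(imp) > 1 else np.nan,
                       median_imp=np.median(imp), min_imp=imp.min(),
                       max_imp=imp.max(),
                       range_flag=bool(((imp < 0) | (imp > 4)).any()))
        else:
            row = dict(dataset=d, mean_imp=np.nan, sd_imp=np.nan,
                       median_imp=np.nan, min_imp=np.nan, max_imp=np.nan,
                       range_flag=False)
        row.update(stats_obs)
        row["mean_diff"] = row["mean_imp"] - row["mean_obs"]
        rows.append(row)
    return pd.DataFrame(rows)
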