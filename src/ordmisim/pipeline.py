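"""End-to-end orchestration of the simulation study.

One replicate = draw a sample without replacement from the synthetic
population, fit the complete-data Cox model (the per-replicate truth),
ampute ECOG under the scenario's mechanism and proportion, let every engine
impute, fit the Cox model on each completed dataset, pool with Rubin's rules
(complete-case analysis is a single fit), and record estimates, CIs and
diagnostics.  Seeding is counter-based -- every random stream is derived
from (master seed, scenario index, replicate index, stream tag) -- so
results are bit-identical regardless of worker count or execution order,
and a restarted run never recomputes a finished replicate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import io as _io
from ._design import MISSING
from .amputation import AmputationConfig, ampute, default_mar_weights
from .imputers import ENGINES, ImputationError, build_predictors, complete_cases
from .performance import ScenarioSpec, compute_metrics, scenario_grid
from .registry_synth import GeneratorConfig, generate_population, sample_population
from .survival import ECOG_TERMS, fit_cox, rubin_pool

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["scenario", "replicate", "method", "term", "truth",
                  "estimate", "variance", "ci_low", "ci_high", "failed",
                  "mean_diff", "realized_proportion"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sizes: tuple = (500, 1000)
    proportions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    mechanisms: tuple = ("MCAR", "MAR", "MNAR")
    engines: tuple = ("pmm", "polr", "polyreg", "rf", "jm", "cca")
    engine_options: dict = field(default_factory=dict)
    mar_weights: dict | None = None
    analysis_terms: str = "adjusted"
    n_sim: int = 100
    seed: int = 0
    workers: int = 1
    out_dir: str = "results"

    def validate(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        unknown = [e for e in self.engines if e not in ENGINES and e != "cca"]
        if unknown:
            raise ValueError(f"unknown engines: {unknown}")
        if not self.sizes or not self.proportions or not self.mechanisms:
            raise ValueError("scenario factors must be non-empty")

    def grid(self) -> list:
        return scenario_grid(self.sizes, self.proportions, self.mechanisms)

    def fingerprint(self) -> str:
        """Hash of everything that determines replicate results; run-shape
        fields (n_sim, workers, out_dir) are excluded so a lengthened or
        re-parallelised run can resume its finished replicates."""
        plain = _io._to_plain(self)
        for transient in ("n_sim", "workers", "out_dir"):
            plain.pop(transient, None)
        payload = json.dumps(plain, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stream(master_seed: int, scenario_index: int, replicate: int, tag: str):
    """Deterministic, scheduling-independent seed stream."""
    return np.random.default_rng(np.random.SeedSequence(
        [int(master_seed), int(scenario_index), int(replicate),
         zlib.crc32(tag.encode())]))


def _method_rows(base, method, pooled, truth, mean_diff=None, failed=False):
    rows = []
    for j, term in enumerate(ECOG_TERMS):
        row = dict(base, method=method, term=term,
                   truth=(np.nan if truth is None else truth.params[term]),
                   failed=failed, mean_diff=mean_diff)
        if pooled is None or failed:
            row.update(estimate=np.nan, variance=np.nan,
                       ci_low=np.nan, ci_high=np.nan)
        else:
            row.update(estimate=pooled.q[j], variance=pooled.T[j],
                       ci_low=pooled.ci_lower[j], ci_high=pooled.ci_upper[j])
        rows.append(row)
    return rows


def run_replicate(population: pd.DataFrame, spec: ScenarioSpec, engines,
                  master_seed: int, scenario_index: int, replicate: int,
                  engine_options: dict | None = None,
                  mar_weights: dict | None = None,
                  analysis_terms: str = "adjusted") -> list:
    """Run one replicate of one scenario; returns tidy record rows.

    Engine and Cox failures are captured as flags on the affected method's
    rows; they never abort the replicate.
    """
    engine_options = engine_options or {}
    cohort = sample_population(
        population, spec.n, _stream(master_seed, scenario_index, replicate, "sample"))
    truth = fit_cox(cohort, terms=analysis_terms)
    base = dict(scenario=spec.scenario_id, replicate=replicate,
                realized_proportion=np.nan)

    if truth.failed:
        logger.warning("replicate %s/%d: complete-data fit failed (%s)",
                       spec.scenario_id, replicate, truth.failure_reason)
        return [r for m in engines
                for r in _method_rows(base, m, None, None, failed=True)]

    if spec.proportion <= 0:
        amputed, realized = cohort, 0.0
    else:
        amp_cfg = AmputationConfig(
            mechanism=spec.mechanism, proportion=spec.proportion,
            weights=(mar_weights or default_mar_weights())
            if spec.mechanism == "MAR" else None,
            seed=_stream(master_seed, scenario_index, replicate, "ampute"))
        amputed, realized, _ = ampute(cohort, amp_cfg)
    base["realized_proportion"] = realized

    predictors = build_predictors(amputed)
    any_missing = (amputed["ecog"].to_numpy() == MISSING).any()
    if not any_missing:
        # degenerate scenario: every engine is the identity, every completed
        # dataset equals the complete cohort, so every method's estimate is
        # the truth itself (B = 0)
        rows = []
        for method in engines:
            if method == "cca":
                pooled = rubin_pool(
                    truth.params[ECOG_TERMS].to_numpy()[None, :],
                    truth.cov.loc[ECOG_TERMS, ECOG_TERMS].to_numpy()[None, :, :],
                    names=ECOG_TERMS)
            else:
                m = engine_options.get(method, {}).get("m", 5)
                est = np.tile(truth.params[ECOG_TERMS].to_numpy(), (m, 1))
                cov = np.tile(
                    truth.cov.loc[ECOG_TERMS, ECOG_TERMS].to_numpy(),
                    (m, 1, 1))
                pooled = rubin_pool(est, cov, names=ECOG_TERMS,
                                    df_complete=truth.df_complete)
                # the mean of m identical estimates is the estimate itself;
                # avoid the 1-ulp drift of the floating-point average
                pooled.q[:] = truth.params[ECOG_TERMS].to_numpy()
            rows += _method_rows(base, method, pooled, truth)
        return rows

    rows = []
    for method in engines:
        if method == "cca":
            cc = complete_cases(amputed)
            if cc.failed:
                rows += _method_rows(base, "cca", None, truth, failed=True)
                continue
            fit = fit_cox(cc.cohort, terms=analysis_terms,
                          warm_start=truth.params)
            if fit.failed:
                rows += _method_rows(base, "cca", None, truth, failed=True)
                continue
            pooled = rubin_pool(
                fit.params[ECOG_TERMS].to_numpy()[None, :],
                fit.cov.loc[ECOG_TERMS, ECOG_TERMS].to_numpy()[None, :, :],
                names=ECOG_TERMS)
            rows += _method_rows(base, "cca", pooled, truth)
            continue

        opts = dict(engine_options.get(method, {}))
        rng = _stream(master_seed, scenario_index, replicate, f"engine:{method}")
        try:
            result = ENGINES[method](amputed, predictors=predictors,
                                     seed=rng, **opts)
        except ImputationError as exc:
            logger.warning("replicate %s/%d: engine %s failed: %s",
                           spec.scenario_id, replicate, method, exc)
            rows += _method_rows(base, method, None, truth, failed=True)
            continue

        fits = [fit_cox(ds, terms=analysis_terms, warm_start=truth.params)
                for ds in result.datasets]
        if any(f.failed for f in fits):
            rows += _method_rows(base, method, None, truth, failed=True)
            continue
        if any_missing:
            mean_diff = float(np.nanmean(
                [d["mean_imp"] - d["mean_obs"] for d in result.diagnostics]))
        else:
            mean_diff = np.nan
        est = np.stack([f.params[ECOG_TERMS].to_numpy() for f in fits])
        cov = np.stack([f.cov.loc[ECOG_TERMS, ECOG_TERMS].to_numpy()
                        for f in fits])
        pooled = rubin_pool(est, cov, names=ECOG_TERMS,
                            df_complete=fits[0].df_complete)
        rows += _method_rows(base, method, pooled, truth, mean_diff=mean_diff)
    return rows


def run_study(config: RunConfig):
    """Run the full factorial study; writes records, summaries and a manifest.

    Returns ``(summary, records)`` DataFrames.  Re-running with an unchanged
    config resumes: replicates already present in ``records.csv`` under the
    same config fingerprint are not recomputed.
    """
    config.validate()
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_probe").write_text("")
        (out / ".write_probe").unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc

    t0 = _time.time()
    fingerprint = config.fingerprint()
    records_path = out / "records.csv"
    manifest_path = out / "manifest.json"

    done = pd.DataFrame(columns=RECORD_COLUMNS)
    completed = set()
    if records_path.exists() and manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("config_fingerprint") == fingerprint:
            done = pd.read_csv(records_path)
            completed = set(zip(done["scenario"], done["replicate"]))
            logger.info("resuming: %d completed replicates found", len(completed) )

    logger.info("generating population of %d", config.generator.population_size)
    population = generate_population(config.generator)
    grid = config.grid()

    tasks = [(si, spec, rep) for si, spec in enumerate(grid)
             for rep in range(config.n_sim)
             if (spec.scenario_id, rep) not in completed]

    def one(si, spec, rep):
        return run_replicate(population, spec, config.engines, config.seed,
                             si, rep, engine_options=config.engine_options,
                             mar_weights=config.mar_weights,
                             analysis_terms=config.analysis_terms)

    if config.workers > 1 and tasks:
        chunks = Parallel(n_jobs=config.workers)(
            delayed(one)(si, spec, rep) for si, spec, rep in tasks)
    else:
        chunks = []
        last_scenario = None
        for si, spec, rep in tasks:
            if spec.scenario_id != last_scenario:
                logger.info("scenario %s (%d/%d)", spec.scenario_id, si + 1,
                            len(grid))
                last_scenario = spec.scenario_id
            chunks.append(one(si, spec, rep))

    new = pd.DataFrame([r for c in chunks for r in c], columns=RECORD_COLUMNS)
    records = pd.concat([done, new], ignore_index=True) if len(done) else new
    records = records.sort_values(["scenario", "replicate", "method", "term"],
                                  kind="stable").reset_index(drop=True)
    records.to_csv(records_path, index=False)

    summary = compute_metrics(records)
    summary.to_csv(out / "summary.csv", index=False)

    import ordmisim
    manifest = {
        "config_fingerprint": fingerprint,
        "master_seed": config.seed,
        "n_sim": config.n_sim,
        "engines": list(config.engines),
        "scenarios": [s.scenario_id for s in grid],
        "replicates_computed": len(tasks),
        "replicates_total": len(records[["scenario", "replicate"]].drop_duplicates()),
        "package_version": ordmisim.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "wall_time_s": round(_time.time() - t0, 2),
        "config": json.loads(json.dumps(_io._to_plain(config), default=str)),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("study finished in %.1f s (%d new replicates)",
                manifest["wall_time_s"], len(new))
    return summary, records
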