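"""Rejection-ABC over the scenario catalog: reference tables, model choice
with Bayes factors, parameter posteriors with 95% HPD intervals, and
recovery/coverage harnesses.

The reference table holds one row per simulation: scenario id, the prior
draw (``par_*`` columns) and the summary vector (``ss_*`` columns).  Summaries
are centered/scaled by table median and MAD; rejection keeps the nearest
fraction of rows by Euclidean distance with Epanechnikov weights.  Model
probabilities are weighted acceptance fractions under equal scenario priors
(1/7); group Bayes factors are posterior odds over prior odds.

Each row's random stream is derived from (seed, scenario id, row index), so
tables are reproducible and extendable chunk-wise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import LocusConfig, SampleConfig, simulate_dataset
from .demography import ScenarioSpec, build_model, sample_prior
from .errors import InputError
from .sumstats import SummaryConfig, summary_vector

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.005  # accepted fraction of rows

#: scenario groupings reported alongside single-scenario probabilities:
#: Tiwi-outgroup histories (4-6) and Tiwi+Galiwin'ku-clade histories (1-2)
DEFAULT_GROUPS = {"4-6": (4, 5, 6), "1-2": (1, 2)}


@dataclass
class ABCSimConfig:
    """Desk-scale per-row simulation settings for reference tables."""

    samples: SampleConfig = field(default_factory=lambda: SampleConfig(
        diploids={"TIW": 8, "GAL": 8, "TIJ": 7, "YAR": 8, "PNG": 8, "OUT": 4}))
    locus: LocusConfig = field(default_factory=lambda: LocusConfig(
        n_loci=40, length_bp=100_000))
    summary: SummaryConfig = field(default_factory=SummaryConfig)


@dataclass
class ReferenceTable:
    table: pd.DataFrame            # scenario_id + par_* + ss_* columns
    meta: dict

    @property
    def ss_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("ss_")]

    @property
    def par_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("par_")]

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)
        with open(path + ".meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "ReferenceTable":
        table = pd.read_csv(path)
        try:
            with open(path + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(table=table, meta=meta)


@dataclass
class AcceptResult:
    indices: np.ndarray   # positions into the table, sorted by distance
    weights: np.ndarray   # Epanechnikov kernel weights
    distances: np.ndarray


@dataclass
class ABCPosterior:
    model_probabilities: dict[int, float]
    bayes_factors: dict[str, float]
    group_probabilities: dict[str, float]
    accepted: AcceptResult


# ---------------------------------------------------------------------------
# reference table generation
# ---------------------------------------------------------------------------

def _row_seed(seed: int, scenario_id: int, row: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed), int(scenario_id), int(row), salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 2)) + 1


def simulate_row(scenario: ScenarioSpec, seed: int, row: int,
                 config: ABCSimConfig) -> tuple[dict[str, float], pd.Series]:
    """One reference-table row: prior draw -> dataset -> summary vector."""
    params = sample_prior(scenario, _row_seed(seed, scenario.id, row, salt=1))
    model = build_model(scenario, params)
    ds = simulate_dataset(model, config.samples, config.locus,
                          seed=_row_seed(seed, scenario.id, row, salt=2))
    return params, summary_vector(ds, config.summary)


def generate_reference_table(catalog: list[ScenarioSpec], n_per_scenario: int,
                             config: ABCSimConfig | None = None, seed: int = 1,
                             row_range: tuple[int, int] | None = None,
                             ) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario (resumable: rows are
    seeded by (seed, scenario, row), so ``row_range`` chunks can be generated
    independently and concatenated)."""
    config = config or ABCSimConfig()
    lo, hi = row_range or (0, n_per_scenario)
    records = []
    failures = []
    for scenario in catalog:
        for i in range(lo, hi):
            try:
                params, ss = simulate_row(scenario, seed, i, config)
            except Exception as exc:  # record and skip
                failures.append({"scenario": scenario.id, "row": i, "error": str(exc)})
                logger.warning("row (scenario %s, %s) failed: %s", scenario.id, i, exc)
                continue
            rec = {"scenario_id": scenario.id}
            rec.update({f"par_{k}": v for k, v in params.items()})
            rec.update({f"ss_{k}": v for k, v in ss.items()})
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    meta = {"seed": int(seed), "n_per_scenario": int(n_per_scenario),
            "row_range": [int(lo), int(hi)],
            "scenarios": {s.id: s.topology for s in catalog},
            "failures": failures,
            "config": {"n_loci": config.locus.n_loci,
                       "length_bp": config.locus.length_bp,
                       "mu": config.locus.mu,
                       "diploids": config.samples.diploids}}
    return ReferenceTable(table=table, meta=meta)


# ---------------------------------------------------------------------------
# normalization and rejection
# ---------------------------------------------------------------------------

def normalize_summaries(table: ReferenceTable | pd.DataFrame,
                        observed: pd.Series,
                        ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Center/scale each summary by table median and MAD; zero-MAD summaries
    are dropped (with a warning).  The observed vector is transformed with
    the table's constants."""
    df = table.table if isinstance(table, ReferenceTable) else table
    ss_cols = [c for c in df.columns if c.startswith("ss_")]
    obs = observed.copy()
    obs.index = [c if c.startswith("ss_") else f"ss_{c}" for c in obs.index]
    missing = [c for c in ss_cols if c not in obs.index]
    if missing:
        raise InputError(f"observed vector lacks summaries {missing[:5]}...")
    X = df[ss_cols]
    med = X.median(axis=0)
    mad = (X - med).abs().median(axis=0)
    keep = [c for c in ss_cols if mad[c] > 0]
    dropped = [c for c in ss_cols if mad[c] == 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-MAD summaries: {dropped[:4]}...")
    Xs = (X[keep] - med[keep]) / mad[keep]
    obs_s = (obs[keep] - med[keep]) / mad[keep]
    scaler = {"median": med[keep].to_dict(), "mad": mad[keep].to_dict(),
              "dropped": dropped}
    return Xs, obs_s, scaler


def abc_reject(table: ReferenceTable | pd.DataFrame, observed: pd.Series,
               tolerance: float = DEFAULT_TOLERANCE) -> AcceptResult:
    """Keep the nearest ceil(tolerance * rows) rows by Euclidean distance in
    normalized summary space, with Epanechnikov weights."""
    if not 0 < tolerance <= 1:
        raise InputError("tolerance must be in (0, 1]")
    df = table.table if isinstance(table, ReferenceTable) else table
    if len(df) == 0:
        raise InputError("empty reference table")
    Xs, obs_s, _ = normalize_summaries(table, observed)
    d = np.sqrt(((Xs.to_numpy() - obs_s.to_numpy()) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(d)))
    order = np.argsort(d, kind="stable")[:n_keep]
    dk = d[order]
    dmax = dk[-1] if dk[-1] > 0 else 1.0
    w = 1.0 - (dk / dmax) ** 2
    if w.sum() <= 0:  # all accepted at the boundary (or single row)
        w = np.ones_like(dk)
    w = w / w.sum()
    return AcceptResult(indices=order, weights=w, distances=dk)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def model_posterior(table: ReferenceTable | pd.DataFrame, accepted: AcceptResult,
                    groups: dict[str, tuple[int, ...]] | None = None,
                    ) -> ABCPosterior:
    """Weighted acceptance fractions per scenario (equal priors) and Bayes
    factors for scenario pairs and the configured groups."""
    df = table.table if isinstance(table, ReferenceTable) else table
    if len(accepted.indices) == 0:
        raise InputError("empty accepted set")
    groups = DEFAULT_GROUPS if groups is None else groups
    all_ids = sorted(df["scenario_id"].unique())
    ids = df["scenario_id"].to_numpy()[accepted.indices]
    probs = {}
    for sid in all_ids:
        probs[int(sid)] = float(accepted.weights[ids == sid].sum())
    bf: dict[str, float] = {}
    for i in all_ids:
        for j in all_ids:
            if i < j:
                pi, pj = probs[int(i)], probs[int(j)]
                bf[f"{i}vs{j}"] = pi / pj if pj > 0 else float("inf")
    gprobs = {}
    n_models = len(all_ids)
    for name, members in groups.items():
        pg = sum(probs.get(int(m), 0.0) for m in members)
        gprobs[name] = pg
        prior_odds = len(members) / (n_models - len(members))
        rest = 1.0 - pg
        bf[f"{name}vs-rest"] = (pg / rest) / prior_odds if rest > 0 else float("inf")
    return ABCPosterior(model_probabilities=probs, bayes_factors=bf,
                        group_probabilities=gprobs, accepted=accepted)


def model_posterior_rf(table: ReferenceTable | pd.DataFrame,
                       observed: pd.Series | np.ndarray,
                       n_estimators: int = 500, seed: int = 0,
                       groups: dict[str, tuple[int, ...]] | None = None,
                       _cache: dict | None = None) -> ABCPosterior:
    """Random-forest model choice (the ABC-RF route): a forest is trained on
    the table's summaries, augmented with linear-discriminant axes, and the
    posterior over scenarios is the forest's class-probability vote for the
    observed vector.

    ``_cache`` (a dict) lets callers reuse the fitted forest across many
    observed vectors.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier

    df = table.table if isinstance(table, ReferenceTable) else table
    ss_cols = [c for c in df.columns if c.startswith("ss_")]
    groups = DEFAULT_GROUPS if groups is None else groups
    key = (id(df), n_estimators, seed)
    fitted = (_cache or {}).get(key)
    if fitted is None:
        X = df[ss_cols].to_numpy()
        y = df["scenario_id"].to_numpy()
        lda = LinearDiscriminantAnalysis(
            n_components=min(len(np.unique(y)) - 1, X.shape[1]))
        lda.fit(X, y)
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=seed, n_jobs=1)
        clf.fit(np.hstack([X, lda.transform(X)]), y)
        fitted = (lda, clf)
        if _cache is not None:
            _cache[key] = fitted
    lda, clf = fitted
    if isinstance(observed, pd.Series):
        obs = observed.copy()
        obs.index = [c if c.startswith("ss_") else f"ss_{c}" for c in obs.index]
        vec = obs[ss_cols].to_numpy(dtype=float)
    else:
        vec = np.asarray(observed, dtype=float)
    proba = clf.predict_proba(np.hstack([vec, lda.transform([vec])[0]])[None, :])[0]
    probs = {int(c): float(p) for c, p in zip(clf.classes_, proba)}
    bf: dict[str, float] = {}
    ids = sorted(probs)
    for i in ids:
        for j in ids:
            if i < j:
                bf[f"{i}vs{j}"] = probs[i] / probs[j] if probs[j] > 0 else float("inf")
    gprobs = {}
    for name, members in groups.items():
        pg = sum(probs.get(int(m), 0.0) for m in members)
        gprobs[name] = pg
        prior_odds = len(members) / (len(ids) - len(members))
        rest = 1.0 - pg
        bf[f"{name}vs-rest"] = (pg / rest) / prior_odds if rest > 0 else float("inf")
    empty = AcceptResult(indices=np.empty(0, dtype=int),
                         weights=np.empty(0), distances=np.empty(0))
    return ABCPosterior(model_probabilities=probs, bayes_factors=bf,
                        group_probabilities=gprobs, accepted=empty)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    # midpoint convention: mass of draw i sits at cumweight - w_i/2
    centers = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, centers, v))


def _weighted_hpd(values: np.ndarray, weights: np.ndarray,
                  mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval over sorted draws containing >= ``mass`` of the
    weighted posterior mass."""
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    cw = np.concatenate([[0.0], np.cumsum(w)])
    best = (float(v[0]), float(v[-1]))
    best_width = v[-1] - v[0]
    j = 0
    for i in range(len(v)):
        j = max(j, i)
        while j < len(v) and cw[j + 1] - cw[i] < mass:
            j += 1
        if j == len(v):
            break
        width = v[j] - v[i]
        if width < best_width:
            best_width = width
            best = (float(v[i]), float(v[j]))
    return best


def estimate_parameters(table: ReferenceTable | pd.DataFrame,
                        accepted: AcceptResult, scenario_id: int,
                        adjust: bool = False,
                        observed: pd.Series | None = None,
                        mass: float = 0.95) -> pd.DataFrame:
    """Posterior median and HPD interval per parameter, from the accepted
    rows of one scenario.

    With ``adjust`` (requires ``observed``), accepted parameter draws are
    shifted by a weighted local-linear regression on the normalized
    summaries before the quantiles are taken.
    """
    df = table.table if isinstance(table, ReferenceTable) else table
    sub_idx = accepted.indices
    ids = df["scenario_id"].to_numpy()[sub_idx]
    sel = ids == scenario_id
    if not sel.any():
        raise InputError(f"no accepted rows for scenario {scenario_id}")
    rows = df.iloc[sub_idx[sel]]
    w = accepted.weights[sel]
    w = w / w.sum()
    par_cols = [c for c in rows.columns if c.startswith("par_")
                and rows[c].notna().all()]
    values = {c: rows[c].to_numpy(dtype=float) for c in par_cols}

    if adjust:
        if observed is None:
            raise InputError("regression adjustment requires the observed vector")
        from sklearn.linear_model import LinearRegression
        Xs, obs_s, _ = normalize_summaries(table, observed)
        Xa = Xs.to_numpy()[sub_idx[sel]]
        delta = Xa - obs_s.to_numpy()
        for c in par_cols:
            reg = LinearRegression()
            reg.fit(delta, values[c], sample_weight=w)
            values[c] = values[c] - delta @ reg.coef_

    out = []
    for c in par_cols:
        v = values[c]
        if np.allclose(v, v[0]):
            med, lo, hi, flag = float(v[0]), float(v[0]), float(v[0]), True
        else:
            med = _weighted_median(v, w)
            lo, hi = _weighted_hpd(v, w, mass=mass)
            flag = False
        out.append({"parameter": c.removeprefix("par_"), "median": med,
                    "hpd_low": lo, "hpd_high": hi, "degenerate": flag})
    return pd.DataFrame(out).set_index("parameter")


# ---------------------------------------------------------------------------
# validation harnesses
# ---------------------------------------------------------------------------

def recovery_experiment(scenario: ScenarioSpec, true_params: dict[str, float],
                        n_trials: int, table: ReferenceTable,
                        seed: int = 1, tolerance: float = DEFAULT_TOLERANCE,
                        config: ABCSimConfig | None = None,
                        parameters: list[str] | None = None) -> dict:
    """Simulate pseudo-observed datasets at ``true_params``, run rejection
    against the scenario's rows of ``table`` and score posterior-median
    relative error and 95% HPD coverage per parameter."""
    config = config or ABCSimConfig()
    df = table.table
    sub = ReferenceTable(df[df["scenario_id"] == scenario.id].reset_index(drop=True),
                         meta=table.meta)
    if len(sub.table) == 0 and n_trials > 0:
        raise InputError(f"table has no rows for scenario {scenario.id}")
    params = parameters or [k for k in true_params
                            if f"par_{k}" in df.columns]
    model = build_model(scenario, true_params) if n_trials > 0 else None
    per_param: dict[str, dict[str, list[float]]] = {
        k: {"rel_err": [], "covered": []} for k in params}
    for t in range(n_trials):
        ds = simulate_dataset(model, config.samples, config.locus,
                              seed=_row_seed(seed, scenario.id, t, salt=7))
        obs = summary_vector(ds, config.summary)
        acc = abc_reject(sub, obs, tolerance=tolerance)
        est = estimate_parameters(sub, acc, scenario.id)
        for k in params:
            truth = true_params[k]
            row = est.loc[k]
            if truth != 0:
                per_param[k]["rel_err"].append(abs(row["median"] - truth) / abs(truth))
            per_param[k]["covered"].append(
                float(row["hpd_low"] <= truth <= row["hpd_high"]))
    report = {"n_trials": n_trials, "parameters": {}}
    for k in params:
        r = per_param[k]
        report["parameters"][k] = {
            "median_rel_error": float(np.median(r["rel_err"])) if r["rel_err"] else None,
            "hpd_coverage": float(np.mean(r["covered"])) if r["covered"] else None,
        }
    return report


def model_choice_experiment(table: ReferenceTable, true_scenario: ScenarioSpec,
                            true_params: dict[str, float] | None, n_trials: int,
                            seed: int = 1, tolerance: float = DEFAULT_TOLERANCE,
                            config: ABCSimConfig | None = None,
                            method: str = "rf",
                            true_model=None) -> dict:
    """Pseudo-observed data from one scenario; count how often that scenario
    attains the highest posterior probability.

    ``method`` selects the model-choice engine: "rf" (random forest on the
    summaries, the default) or "rejection" (weighted acceptance fractions).
    ``true_model`` may supply a pre-built generating model (e.g. the
    calibrated fixture with epoch structure); otherwise it is built from
    ``true_params``.
    """
    config = config or ABCSimConfig()
    model = true_model if true_model is not None else \
        build_model(true_scenario, true_params)
    cache: dict = {}
    wins = 0
    top: list[int] = []
    p_true: list[float] = []
    for t in range(n_trials):
        ds = simulate_dataset(model, config.samples, config.locus,
                              seed=_row_seed(seed, true_scenario.id, t, salt=9))
        obs = summary_vector(ds, config.summary)
        if method == "rf":
            post = model_posterior_rf(table, obs, seed=seed, _cache=cache)
        elif method == "rejection":
            acc = abc_reject(table, obs, tolerance=tolerance)
            post = model_posterior(table, acc)
        else:
            raise InputError(f"unknown model-choice method {method!r}")
        best = max(post.model_probabilities, key=post.model_probabilities.get)
        top.append(best)
        p_true.append(post.model_probabilities.get(true_scenario.id, 0.0))
        wins += int(best == true_scenario.id)
    return {"n_trials": n_trials, "wins": wins,
            "win_rate": wins / n_trials if n_trials else None,
            "mean_p_true": float(np.mean(p_true)) if p_true else None,
            "top_scenarios": top}
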