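"""End-to-end orchestration: cohort -> classification -> maps -> statistics.

``run_pipeline`` drives the full analysis from either a cohort file or a
synthetic-generation config and writes a machine-readable JSON report,
per-table TSVs, and the figures.  Everything downstream of the seed is
deterministic: the same config and seed yield an identical report.

The three report builders mirror the reference study's presentation:

* ``report_table2`` — per-domain impairment rates per group with
  unadjusted 2x2 odds ratios (NA on zero cells), Fisher exact p-values
  and Benjamini–Hochberg q-values across the 20-domain family;
* ``report_table3`` — per score domain: Cohen's d, Welch and
  Mann–Whitney tests, bootstrapped t-test, and wild-bootstrap regression
  coefficients with BCa intervals, unadjusted and adjusted for sex,
  mother's education (ordinal), neonatal brain injury and neonatal
  morbidity;
* ``report_fig2`` — the group x burden-value contingency table and its
  likelihood-ratio G test (df follows the observed burden values).
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

from . import __version__
from .classify import ImpairmentMatrix, build_impairment_matrix, \
    write_impairment_matrix
from .cohort import CohortTable, Group, read_cohort
from .maps import burden_profile, edges_at_threshold, exceeds_reference_max, \
    incidence_sum, pair_counts, total_impaired_pairs, BurdenProfile
from .plotting import render_burden_histogram, render_relationship_map
from .simulate import SyntheticConfig, generate_cohort
from .stats import bh_fdr, bootstrap_t, cohen_d, cumulative_logit_or, \
    fisher_exact, likelihood_ratio_test, mann_whitney, odds_ratio_2x2, \
    welch_t, wild_bootstrap_regression
from .classify import classify_mnd, impute_group_median

log = logging.getLogger("comorbmap")

MODEL1_COVARIATES = ("sex", "mother_education", "brain_injury", "morbidity")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int
    input: str | Path | SyntheticConfig | None = None
    out_dir: str | Path = "comorbmap_out"
    thresholds: tuple[int, ...] = (1, 5, 10)
    sipt_inclusive: bool = False
    impute_group_median_domains: tuple[tuple[str, str], ...] = ()
    bootstrap_t_resamples: int = 1000
    wild_bootstrap_resamples: int = 2000
    fdr_level: float = 0.05
    make_figures: bool = True
    figure_format: str = "svg"

    def __post_init__(self) -> None:
        ts = self.thresholds
        if not ts or any(t < 1 for t in ts) or list(ts) != sorted(set(ts)):
            raise ValueError(
                "thresholds must be strictly increasing positive integers")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.bootstrap_t_resamples < 100 or self.wild_bootstrap_resamples < 100:
            raise ValueError("bootstrap resample counts must be >= 100")

    def config_hash(self) -> str:
        payload = repr(dataclasses.asdict(self)) if not isinstance(
            self.input, SyntheticConfig) else repr(
            (dataclasses.asdict(dataclasses.replace(self, input=None)),
             repr(self.input)))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All pipeline outputs in memory, mirrored to disk by run_pipeline."""

    config_hash: str
    seed: int
    table2: pd.DataFrame
    table3: pd.DataFrame
    mnd_ordinal: dict
    fig2: dict
    burden: dict
    maps: dict
    files: dict[str, str] = field(default_factory=dict)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if v != v else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def report_table2(matrix: ImpairmentMatrix,
                  fdr_level: float = 0.05) -> pd.DataFrame:
    """Impairment rates, unadjusted ORs and BH q-values per domain."""
    rows = []
    for j, domain in enumerate(matrix.domains):
        e = matrix.group_mask(Group.EPT)
        t = matrix.group_mask(Group.TERM)
        a = int(matrix.calls[e, j].sum())
        na = int(matrix.observed[e, j].sum())
        c = int(matrix.calls[t, j].sum())
        nc = int(matrix.observed[t, j].sum())
        row = {
            "domain": domain,
            "ept_impaired": a, "ept_assessed": na,
            "ept_pct": 100 * a / na if na else float("nan"),
            "term_impaired": c, "term_assessed": nc,
            "term_pct": 100 * c / nc if nc else float("nan"),
        }
        if na == 0 or nc == 0:
            row.update(odds_ratio=float("nan"), or_ci_low=float("nan"),
                       or_ci_high=float("nan"), p_value=float("nan"),
                       note="no observed data in a group")
        else:
            orr = odds_ratio_2x2(a, na - a, c, nc - c)
            p = fisher_exact(a, na - a, c, nc - c).p_value
            row.update(odds_ratio=orr.odds_ratio, or_ci_low=orr.ci_low,
                       or_ci_high=orr.ci_high, p_value=p, note=None)
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    df["q_value"] = q
    df["significant"] = df["q_value"] <= fdr_level
    return df


def _model_frame(cohort: CohortTable, domain: str,
                 adjusted: bool) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Design matrix and response for one domain's regression."""
    rows, y, ids = [], [], []
    for c in cohort.children:
        score = c.scores.get(domain)
        if score is None:
            continue
        base = [1.0, 1.0 if c.group is Group.EPT else 0.0]
        if adjusted:
            base += [1.0 if c.sex == "M" else 0.0,
                     float(int(c.mother_education)),
                     float(c.brain_injury), float(c.morbidity)]
        rows.append(base)
        y.append(score)
        ids.append(c.child_id)
    names = ["intercept", "group_EPT"]
    if adjusted:
        names += ["sex_M", "mother_education", "brain_injury", "morbidity"]
    return np.asarray(rows), np.asarray(y), names, ids


def report_table3(cohort: CohortTable, seed: int,
                  bootstrap_t_resamples: int = 1000,
                  wild_bootstrap_resamples: int = 2000,
                  fdr_level: float = 0.05) -> pd.DataFrame:
    """Group comparisons per score domain with bootstrap validation."""
    rng = np.random.default_rng(seed)
    rows = []
    for spec in cohort.registry.score_domains:
        d = spec.abbreviation
        x = np.array([c.scores[d] for c in cohort.group(Group.EPT)
                      if d in c.scores], dtype=float)
        yv = np.array([c.scores[d] for c in cohort.group(Group.TERM)
                       if d in c.scores], dtype=float)
        if len(x) < 2 or len(yv) < 2:
            log.warning("domain %s skipped: fewer than 2 observations in a group", d)
            continue
        wt = welch_t(x, yv)
        mw = mann_whitney(x, yv)
        bt = bootstrap_t(x, yv, bootstrap_t_resamples,
                         seed=int(rng.integers(2 ** 31)))
        row = {
            "domain": d,
            "n_ept": len(x), "n_term": len(yv),
            "cohen_d": cohen_d(x, yv),
            "welch_t": wt.statistic, "welch_p": wt.p_value,
            "mannwhitney_u": mw.statistic, "mannwhitney_p": mw.p_value,
            "boot_t_diff": bt.estimate, "boot_t_ci_low": bt.ci_low,
            "boot_t_ci_high": bt.ci_high, "boot_t_p": bt.p_value,
        }
        for label, adjusted in (("unadj", False), ("adj", True)):
            X, resp, names, _ = _model_frame(cohort, d, adjusted)
            # covariate columns that are constant or collinear within the
            # observed subset (e.g. no brain injury, or morbidity identical
            # to group in a tiny cohort) carry no information; drop them
            # rather than fail
            keep = [0, 1]
            for j in range(2, X.shape[1]):
                cand = X[:, keep + [j]]
                if X[:, j].std() > 0 and \
                        np.linalg.matrix_rank(cand) == len(keep) + 1:
                    keep.append(j)
            if len(keep) < X.shape[1]:
                dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
                log.warning("domain %s (%s): dropping degenerate covariates %s",
                            d, label, dropped)
                X, names = X[:, keep], [names[j] for j in keep]
            reg = wild_bootstrap_regression(
                X, resp, names=names, n_resamples=wild_bootstrap_resamples,
                seed=int(rng.integers(2 ** 31)))
            b, lo, hi = reg.coefficient("group_EPT")
            row[f"{label}_B"] = b
            row[f"{label}_ci_low"] = lo
            row[f"{label}_ci_high"] = hi
            boot = reg.resample_coefficients[:, names.index("group_EPT")]
            # two-sided bootstrap p: smallest level at which the BCa-free
            # percentile interval excludes 0
            p = 2 * min(float(np.mean(boot <= 0)), float(np.mean(boot >= 0)))
            row[f"{label}_p"] = min(max(p, 1 / (len(boot) + 1)), 1.0)
            if adjusted:
                row["adj_r2"] = reg.adj_r_squared
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("unadj", "adj"):
        df[f"{col}_q"] = bh_fdr(df[f"{col}_p"].to_numpy())
    df["boot_t_q"] = bh_fdr(df["boot_t_p"].to_numpy())
    return df


def report_mnd_ordinal(cohort: CohortTable) -> dict:
    """Cumulative-logit OR for the 3-level MND severity by group."""
    outcome, group = [], []
    for c in cohort.children:
        status = classify_mnd(c.touwen_domains)
        if status is None:
            continue
        sev = 0 if status.n_dysfunctional == 0 else (
            1 if status.n_dysfunctional <= 2 else 2)
        outcome.append(sev)
        group.append(1.0 if c.group is Group.EPT else 0.0)
    if len(set(outcome)) < 2 or len(set(group)) < 2:
        return {"odds_ratio": None, "note": "degenerate MND distribution"}
    res = cumulative_logit_or(np.array(outcome), np.array(group))
    out = {"odds_ratio": res.statistic, "p_value": res.p_value,
           "note": res.note}
    if hasattr(res, "ci"):
        out["ci_low"], out["ci_high"] = res.ci
    return out


def report_fig2(profile: BurdenProfile) -> dict:
    """Group x burden contingency table and likelihood-ratio G test."""
    values = sorted({b for b in profile.per_child.values()})
    table = []
    for group in ("EPT", "TERM"):
        hist = profile.histogram(group)
        table.append([hist.get(v, 0) for v in values])
    out = {
        "burden_values": values,
        "counts": {"EPT": table[0], "TERM": table[1]},
    }
    if len(values) < 2:
        out.update(statistic=None, df=None, p_value=None,
                   note="single burden value observed; test skipped")
        return out
    res = likelihood_ratio_test(table)
    out.update(statistic=res.statistic, df=res.df, p_value=res.p_value,
               note=res.note)
    return out


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis and write all outputs under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("pipeline start (config %s, seed %d)", chash, config.seed)

    # --- load or generate -------------------------------------------------
    if isinstance(config.input, SyntheticConfig):
        cohort = generate_cohort(config.input)
    elif config.input is None:
        cohort = generate_cohort(SyntheticConfig(seed=config.seed))
    else:
        cohort = read_cohort(config.input)

    for domain, group in config.impute_group_median_domains:
        cohort = impute_group_median(cohort, domain, group)

    # --- classify ---------------------------------------------------------
    matrix = build_impairment_matrix(cohort,
                                     sipt_inclusive=config.sipt_inclusive)
    files: dict[str, str] = {}
    mpath = out / "impairment_matrix.tsv"
    write_impairment_matrix(matrix, mpath)
    files["impairment_matrix"] = str(mpath)

    # --- burden profile ---------------------------------------------------
    profile = burden_profile(matrix)
    exceed = exceeds_reference_max(profile, Group.TERM)
    burden = {
        "mean_burden": {g: profile.mean_burden(g) for g in ("EPT", "TERM")},
        "max_burden": {g: profile.max_burden(g) for g in ("EPT", "TERM")},
        "histogram": {g: profile.histogram(g) for g in ("EPT", "TERM")},
        "ept_above_term_max": {
            "reference_max": exceed.reference_max,
            "count": exceed.count, "proportion": exceed.proportion},
    }
    fig2 = report_fig2(profile)

    # --- relationship maps ------------------------------------------------
    maps_out: dict = {}
    edge_rows = []
    for group in ("EPT", "TERM"):
        graph = pair_counts(matrix, group)
        per_threshold = {}
        for k in config.thresholds:
            edges = edges_at_threshold(graph, k)
            per_threshold[k] = {
                "n_edges": len(edges),
                "total_impaired_pairs": total_impaired_pairs(graph, k),
                "incidence_sum": incidence_sum(graph, k),
            }
            edge_rows += [
                {"domain_a": a, "domain_b": b, "n_cooccurring": c,
                 "group": group, "threshold": k} for a, b, c in edges]
            if config.make_figures:
                fpath = out / f"map_{group}_k{k}.{config.figure_format}"
                render_relationship_map(graph, k, fpath)
                files[f"map_{group}_k{k}"] = str(fpath)
        maps_out[group] = {
            "node_counts": graph.node_counts,
            "max_pair_count": graph.max_pair_count(),
            "thresholds": per_threshold,
        }
    epath = out / "edges.tsv"
    pd.DataFrame(edge_rows,
                 columns=["domain_a", "domain_b", "n_cooccurring", "group",
                          "threshold"]).to_csv(epath, sep="\t", index=False)
    files["edges"] = str(epath)
    if config.make_figures:
        fpath = out / f"burden_histogram.{config.figure_format}"
        render_burden_histogram(profile, fpath)
        files["burden_histogram"] = str(fpath)

    # --- statistics -------------------------------------------------------
    table2 = report_table2(matrix, config.fdr_level)
    table3 = report_table3(cohort, config.seed,
                           config.bootstrap_t_resamples,
                           config.wild_bootstrap_resamples,
                           config.fdr_level)
    mnd_ord = report_mnd_ordinal(cohort)

    header = f"# comorbmap {__version__} config_hash={chash} seed={config.seed}\n"
    for name, df in (("table2", table2), ("table3", table3)):
        tpath = out / f"{name}.tsv"
        with open(tpath, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        files[name] = str(tpath)

    report = AnalysisReport(
        config_hash=chash, seed=config.seed, table2=table2, table3=table3,
        mnd_ordinal=mnd_ord, fig2=fig2, burden=burden, maps=maps_out,
        files=files)
    payload = {
        "meta": {"package": "comorbmap", "version": __version__,
                 "config_hash": chash, "seed": config.seed},
        "table2": table2.to_dict(orient="records"),
        "table3": table3.to_dict(orient="records"),
        "mnd_ordinal": mnd_ord,
        "fig2": fig2,
        "burden": burden,
        "maps": maps_out,
        "files": files,
    }
    rpath = out / "report.json"
    with open(rpath, "w") as fh:
        json.dump(_json_safe(payload), fh, indent=2, sort_keys=True)
    files["report"] = str(rpath)
    log.info("pipeline done: %s", rpath)
    return report
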