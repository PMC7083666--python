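"""End-to-end orchestration of the metacommunity analysis.

The workflow mirrors a full study: simulate (or ingest) a design, compute
the three route distances, metacommunity connectivity per route, build and
select a spatial weighting matrix, forward-select environmental variables
and positive MEMs, run classical and MSR variation partitioning with
taxon-count standardization (per dispersal-trait group when a trait table
is supplied), fit MLPE distance-decay models per route, test environmental
heterogeneity by PERMDISP (when group labels allow), and compute the
diversity-partition SES.

One master seed deterministically derives all stage seeds through
``numpy.random.SeedSequence.spawn``, so reruns of the same configuration
are byte-identical apart from wall-clock metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import decay, simulate, spatial, structure, varpart as vp
from .geometry import DistanceTriplet, summarize_distances

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Defaults follow the study protocol constants: retain the first 4
    forward-selected environmental variables and positive MEMs, S = 20 taxa
    per standardization replicate repeated 500 times, 999 permutations for
    selection tests and the diversity null, 1000 permutations for PERMDISP,
    and 999 MSR surrogates.
    """

    design: simulate.DesignConfig = field(default_factory=simulate.DesignConfig)
    scenario: simulate.ScenarioConfig = field(default_factory=simulate.ScenarioConfig)
    env_autocorr_range: float = 10.0
    n_env_vars: int = 10
    alpha: float = 0.05
    n_perm: int = 999
    n_null: int = 999
    permdisp_perm: int = 1000
    n_surrogates: int = 999
    S: int = 20
    n_reps: int = 500
    k_retained: int = 4
    use_trait_table: bool = False
    trait_p_high: float = 0.5
    swm_selection: bool = False       # full SWM grid search (slower) or Gabriel/binary
    stages: tuple = ("distances", "connectivity", "varpart", "decay",
                     "dispersion", "diversity")
    seed: int = 0


@dataclass
class RunReport:
    """Per-stage results plus provenance; serializable to JSON."""

    config: dict
    stage_seeds: dict
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {"config": self.config, "stage_seeds": self.stage_seeds,
             "results": self.results, "warnings": self.warnings,
             "errors": self.errors},
            default=_jsonable, **kw)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_seeds(master: int, names) -> dict:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, children)}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all enabled stages in dependency order.

    A failing stage records its error and the remaining independent stages
    still run.  Numeric results live only in the returned report.
    """
    stage_names = ["design", "environment", "community", "traits", "connectivity",
                   "basis", "selection", "varpart", "decay", "dispersion", "diversity"]
    seeds = _stage_seeds(cfg.seed, stage_names)
    report = RunReport(
        config={"design": asdict(cfg.design), "scenario": asdict(cfg.scenario),
                **{k: v for k, v in asdict(cfg).items() if k not in ("design", "scenario")}},
        stage_seeds=seeds,
    )

    cfg.design.seed = seeds["design"]
    cfg.scenario.seed = seeds["community"]
    sites, net, surface = simulate.generate_design(cfg.design)
    env = simulate.generate_environment(
        sites, cfg.env_autocorr_range, cfg.n_env_vars, seed=seeds["environment"])
    triplet = simulate.design_distances(sites, net, surface)
    community = simulate.generate_community(sites, env, triplet, cfg.scenario)
    report.results["design"] = {
        "n_sites": len(sites), "n_taxa": community.n_taxa,
        "distance_summary": summarize_distances(triplet).to_dict(),
    }

    env_t = vp.log1p_env(env - env.min().min())  # shift to positive scale first

    if "connectivity" in cfg.stages:
        try:
            out = {}
            for route, dmat in triplet.items():
                if np.isnan(dmat.to_numpy()).any():
                    report.warnings.append(
                        f"connectivity skipped for {route}: incomplete matrix")
                    continue
                res = conn.average_connectivity(community, dmat, route=route)
                out[route] = {"avg_con": res.avg_con,
                              "con": res.con.round(6).to_dict()}
            report.results["connectivity"] = out
        except Exception as exc:  # pragma: no cover - defensive
            report.errors["connectivity"] = str(exc)

    # spatial basis (needed by varpart)
    basis = None
    sel_env_cols = list(env_t.columns[: cfg.k_retained])
    mems = None
    try:
        Y = vp.hellinger(community)
        geo = triplet["GEO"]
        if cfg.swm_selection:
            cands = spatial.candidate_swms(geo)
            best, table = spatial.select_swm(Y.data, cands, alpha=cfg.alpha,
                                             n_perm=min(cfg.n_perm, 199),
                                             seed=seeds["basis"])
            swm = best if best is not None else cands[0]
            report.results["swm_selection"] = table.to_dict()
        else:
            swm = spatial.build_swm(geo, "gabriel", "binary")
        basis = spatial.compute_mem(swm)
        sel_s = spatial.forward_select(Y.data, basis.positive, alpha=cfg.alpha,
                                       n_perm=min(cfg.n_perm, 199), seed=seeds["selection"])
        sel_e = spatial.forward_select(Y.data, env_t, alpha=cfg.alpha,
                                       n_perm=min(cfg.n_perm, 199), seed=seeds["selection"] + 1)
        mem_cols = sel_s.truncate(cfg.k_retained) if sel_s.significant else []
        env_cols = sel_e.truncate(cfg.k_retained) if sel_e.significant else []
        if not mem_cols:
            report.warnings.append(
                "no MEM passed forward selection; using the first "
                f"{cfg.k_retained} positive MEMs")
            mem_cols = list(basis.positive.columns[: cfg.k_retained])
        if not env_cols:
            report.warnings.append(
                "no environmental variable passed forward selection; using the "
                f"first {cfg.k_retained} columns")
            env_cols = list(env_t.columns[: cfg.k_retained])
        sel_env_cols = env_cols
        mems = basis.positive.loc[:, mem_cols]
        report.results["selection"] = {
            "mem_selected": mem_cols, "env_selected": env_cols,
            "mem_global_p": sel_s.global_p, "env_global_p": sel_e.global_p,
        }
    except Exception as exc:
        report.errors["basis"] = str(exc)

    if "varpart" in cfg.stages and basis is not None and mems is not None:
        try:
            E = env_t.loc[:, sel_env_cols]
            groups = {"all": community}
            if cfg.use_trait_table:
                traits = simulate.generate_trait_table(
                    community, cfg.trait_p_high, seed=seeds["traits"])
                for tr in traits.columns:
                    for cls in ("low", "high"):
                        try:
                            groups[f"{tr}_{cls}"] = vp.subset_by_trait(
                                community, traits, tr, cls)
                        except ValueError as e:
                            report.warnings.append(f"trait group {tr}/{cls}: {e}")
            out = {}
            for gname, com in groups.items():
                gout = {}
                Yg = vp.hellinger(com)
                for adjustment in ("classical", "msr"):
                    res = vp.varpart(
                        Yg, E, mems, adjustment, basis=basis,
                        n_surrogates=min(cfg.n_surrogates, 199), seed=seeds["varpart"])
                    gout[adjustment] = {**res.fractions(),
                                        "identity_gap": res.identity_gap()}
                    S_eff = min(cfg.S, com.n_taxa)
                    std = vp.standardized_varpart(
                        com, E, mems,
                        vp.StandardizationConfig(S=S_eff, n_reps=cfg.n_reps,
                                                 seed=seeds["varpart"] + 1),
                        adjustment, basis=basis,
                        n_surrogates=min(cfg.n_surrogates, 199))
                    gout[adjustment]["standardized"] = {
                        **std.boxplot_stats(), "S": std.S, "n_reps": cfg.n_reps,
                        "n_redrawn": std.n_redrawn}
                out[gname] = gout
            report.results["varpart"] = out
        except Exception as exc:
            report.errors["varpart"] = str(exc)

    if "decay" in cfg.stages:
        try:
            D = decay.bray_curtis(community)
            table = decay.compare_routes(D, triplet, seed=seeds["decay"])
            report.results["decay"] = table.to_dict()
        except Exception as exc:
            report.errors["decay"] = str(exc)

    if "dispersion" in cfg.stages:
        try:
            labels = sites["subbasin_id"]
            if labels.nunique() < 2:
                # single sub-basin designs: split sites along the main axis
                med = sites["x"].median()
                labels = np.where(sites["x"] <= med, "west", "east")
            res = structure.env_heterogeneity(
                env_t, labels, n_perm=cfg.permdisp_perm, seed=seeds["dispersion"])
            report.results["dispersion"] = {
                "F": res.F, "p": res.p, "n_perm": res.n_perm,
                "group_means": res.group_means["mean_dist"].to_dict(),
            }
        except Exception as exc:
            report.errors["dispersion"] = str(exc)

    if "diversity" in cfg.stages:
        try:
            part = structure.diversity_ses(community, n_null=cfg.n_null,
                                           seed=seeds["diversity"])
            report.results["diversity"] = part.summary()
        except Exception as exc:
            report.errors["diversity"] = str(exc)

    return report


def validate_inputs(
    sites: pd.DataFrame | None = None,
    community: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
    distances: dict | None = None,
) -> list[dict]:
    """Machine-readable diagnostics on user-supplied inputs (no analysis run).

    Checks site-id alignment across tables, abundance non-negativity and
    margin totals, and distance-matrix symmetry / diagonal.  Returns a list
    of ``{"check", "severity", "detail"}`` records; an empty list means all
    checks passed.
    """
    diags: list[dict] = []

    def add(check, severity, detail):
        diags.append({"check": check, "severity": severity, "detail": detail})

    site_ids = None
    if sites is not None:
        ids = sites.index if sites.index.name == "site_id" else sites.get("site_id")
        if ids is None:
            add("sites.schema", "error", "no site_id column or index")
        else:
            dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
            if dup:
                add("sites.unique", "error", f"duplicate site ids: {dup}")
            site_ids = pd.Index(ids)
    if community is not None:
        a = community.to_numpy()
        neg = np.argwhere(a < 0)
        for i, j in neg[:10]:
            add("community.nonneg", "error",
                f"negative abundance at site {community.index[i]!r}, "
                f"taxon {community.columns[j]!r}")
        zero_rows = list(community.index[a.sum(axis=1) == 0])
        if zero_rows:
            add("community.margins", "warning", f"sites with zero total: {zero_rows}")
        if site_ids is not None:
            extra = set(community.index) ^ set(site_ids)
            if extra:
                add("community.alignment", "error",
                    f"site-id mismatch with site table: {sorted(extra)}")
    if env is not None and site_ids is not None:
        extra = set(env.index) ^ set(site_ids)
        if extra:
            add("env.alignment", "error", f"site-id mismatch: {sorted(extra)}")
    for name, d in (distances or {}).items():
        m = d.to_numpy(float)
        asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
        if asym > 1e-8:
            add(f"distance.{name}.symmetry", "error", f"max asymmetry {asym:.3g} km")
        if m.size and np.nanmax(np.abs(np.diag(m))) > 1e-12:
            add(f"distance.{name}.diagonal", "error", "nonzero diagonal")
        if (m < -1e-12).any():
            add(f"distance.{name}.nonneg", "error", "negative distances present")
    return diags
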