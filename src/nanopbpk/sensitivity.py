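"""Local and global sensitivity analysis of the PBPK model.

Local analysis (LSA) perturbs one parameter at a time over ±99% of its
reference value and reports the normalized sensitivity coefficient

    SC = [(AUC′ − AUC)/AUC] / [(Par′ − Par)/Par]

per output, ranking parameters by the maximum |SC| over the scan.

Global analysis (GSA) draws Latin hypercube samples over the full
11-dimensional parameter box and scores each parameter by three techniques —
standardized multiple linear regression (MLRA), partial rank correlation
(PRCA) and one-way ANOVA F across equal-count bins — on replicate designs,
then merges the per-technique rankings (Tukey-grouped across replicates)
into a weighted consensus ranking with equal technique weights.

The default parameter space is the 11-parameter set used for the model's
reference analysis: NP radius, density and degradation rate; tumor specific
blood flow, blood viscosity, vascular fraction, pore radius and porosity;
liver and spleen macrophage coverage; hematocrit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SimulationConfig, aggregate_outputs, simulate
from .physiology import default_body, default_tumor
from .transport import NanoparticleSpec

__all__ = [
    "ParameterSpace",
    "LSAResult",
    "GSAResult",
    "OUTPUT_NAMES",
    "default_parameter_space",
    "make_auc_runner",
    "lsa_scan",
    "lhs_sample",
    "evaluate_design",
    "gsa_mlra",
    "gsa_prca",
    "gsa_anova",
    "gsa_weighted_rank",
    "run_gsa",
]

OUTPUT_NAMES = ("auc_plasma", "auc_mps", "auc_tumor", "auc_excreta")

#: a model runner maps a {parameter: value} dict to a {output: value} dict
Runner = Callable[[Dict[str, float]], Dict[str, float]]


@dataclass(frozen=True)
class ParameterSpace:
    """Named parameters with reference values and uniform perturbation bounds.

    Bounds default to ±99% of the reference (uniform); the hematocrit upper
    bound is additionally capped below 1.
    """

    names: Tuple[str, ...]
    reference: Dict[str, float]
    lower: Dict[str, float] = field(default_factory=dict)
    upper: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lower = dict(self.lower)
        upper = dict(self.upper)
        for n in self.names:
            ref = self.reference[n]
            if ref <= 0:
                raise ValueError(f"reference value for {n} must be > 0")
            lower.setdefault(n, 0.01 * ref)
            upper.setdefault(n, 1.99 * ref)
            if n == "hematocrit":
                upper[n] = min(upper[n], 0.99)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def k(self) -> int:
        return len(self.names)

    def bounds(self, name: str) -> Tuple[float, float]:
        return self.lower[name], self.upper[name]


def default_parameter_space() -> ParameterSpace:
    """The 11-parameter reference space (NP, tumor, individual parameters)."""
    ref = {
        "np_radius_nm": 50.0,
        "np_density_g_cm3": 2.0,
        "k_deg_per_h": 0.01,
        "tumor_flow_ml_g_min": 0.1,
        "tumor_viscosity_cP": 7.42,
        "tumor_vascular_fraction": 0.1,
        "tumor_pore_radius_nm": 850.0,
        "tumor_porosity": 0.001,
        "a_mac_liver": 0.5,
        "a_mac_spleen": 0.1,
        "hematocrit": 0.45,
    }
    return ParameterSpace(tuple(ref), ref)


def make_auc_runner(config: Optional[SimulationConfig] = None) -> Runner:
    """Build a model runner returning the four headline AUCs (%ID·h).

    Each call re-assembles the tumor-bearing parameterization with the
    supplied parameter overrides and integrates the full model.
    """
    config = config or SimulationConfig()

    def run(values: Dict[str, float]) -> Dict[str, float]:
        np_spec = NanoparticleSpec(
            radius_nm=values.get("np_radius_nm", 50.0),
            density_g_cm3=values.get("np_density_g_cm3", 2.0),
            k_deg_per_h=values.get("k_deg_per_h", 0.01),
        )
        tumor = default_tumor({
            "specific_blood_flow_ml_g_min": values.get("tumor_flow_ml_g_min", 0.1),
            "viscosity_cP": values.get("tumor_viscosity_cP", 7.42),
            "vascular_fraction": values.get("tumor_vascular_fraction", 0.1),
            "pore_radius_nm": values.get("tumor_pore_radius_nm", 850.0),
            "porosity": values.get("tumor_porosity", 0.001),
        })
        body = default_body({
            "body": {"hematocrit": values.get("hematocrit", 0.45)},
            "phagocyte": {
                "area_fraction_liver": values.get("a_mac_liver", 0.5),
                "area_fraction_spleen": values.get("a_mac_spleen", 0.1),
            },
        })
        res = simulate(np_spec, body=body, tumor=tumor, config=config)
        ag = aggregate_outputs(res, t_max_h=config.t_end_h)
        return {
            "auc_plasma": ag.auc_plasma,
            "auc_mps": ag.auc_mps,
            "auc_tumor": ag.auc_tumor,
            "auc_excreta": ag.auc_excreta,
        }

    return run


# ---------------------------------------------------------------------------
# local sensitivity analysis

@dataclass(frozen=True)
class LSAResult:
    curves: pd.DataFrame      # parameter, output, level, par_value, auc, sc
    max_abs_sc: pd.DataFrame  # rows parameters, columns outputs
    ranks: pd.DataFrame       # rank 1 = most significant, per output
    flagged: Tuple[Tuple[str, str], ...] = ()  # (parameter, output) with AUC_ref = 0


def lsa_scan(
    space: ParameterSpace,
    runner: Runner,
    n_levels: int = 1000,
    outputs: Sequence[str] = OUTPUT_NAMES,
) -> LSAResult:
    """One-at-a-time scan over ±99% of each reference value.

    Levels are equally spaced across each parameter's bounds, excluding the
    exact reference point (where SC is undefined). Parameters are ranked per
    output by max |SC|; ties break by parameter order.
    """
    ref_out = runner(dict(space.reference))
    rows = []
    flagged = []
    for name in space.names:
        lo, hi = space.bounds(name)
        ref = space.reference[name]
        levels = np.linspace(lo, hi, n_levels)
        levels = levels[np.abs(levels - ref) > 1e-12 * max(abs(ref), 1.0)]
        for lev, par in enumerate(levels):
            vals = dict(space.reference)
            vals[name] = float(par)
            out = runner(vals)
            for o in outputs:
                auc_ref = ref_out[o]
                if auc_ref == 0.0:
                    sc = np.nan
                else:
                    sc = ((out[o] - auc_ref) / auc_ref) / ((par - ref) / ref)
                rows.append((name, o, lev, float(par), out[o], sc))
    curves = pd.DataFrame(
        rows, columns=["parameter", "output", "level", "par_value", "auc", "sc"]
    )
    for o in outputs:
        if ref_out[o] == 0.0:
            flagged.extend((n, o) for n in space.names)
    max_abs = (
        curves.pivot_table(index="parameter", columns="output", values="sc",
                           aggfunc=lambda s: s.abs().max(), dropna=False)
        .reindex(index=list(space.names), columns=list(outputs))
    )
    ranks = _rank_table(max_abs, list(space.names))
    return LSAResult(curves, max_abs, ranks, tuple(flagged))


def _rank_table(scores: pd.DataFrame, order: List[str]) -> pd.DataFrame:
    """Rank 1 = largest score; NaN columns excluded; ties break by row order."""
    ranks = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for col in scores.columns:
        s = scores[col]
        if s.isna().all():
            continue
        # stable sort on (-score, declared order)
        key = [(-s[n], order.index(n)) for n in scores.index]
        idx_sorted = [n for _, n in sorted(zip(key, scores.index))]
        for pos, n in enumerate(idx_sorted, start=1):
            ranks.loc[n, col] = pos
    return ranks


# ---------------------------------------------------------------------------
# global sensitivity analysis

def lhs_sample(
    space: ParameterSpace,
    n: int = 5000,
    replicates: int = 10,
    seed: int = 0,
) -> List[pd.DataFrame]:
    """Latin hypercube designs: ``replicates`` independent n×k samples.

    Each parameter's range is split into n equal strata with one uniform
    draw per stratum, and the strata are independently permuted per column.
    A master seed spawns one substream per replicate, so designs are
    reproducible and replicate-distinct.
    """
    if n < 2:
        raise ValueError("LHS needs at least 2 samples")
    streams = np.random.SeedSequence(seed).spawn(replicates)
    designs = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = {}
        for name in space.names:
            lo, hi = space.bounds(name)
            strata = (np.arange(n) + rng.uniform(size=n)) / n
            cols[name] = lo + (hi - lo) * rng.permutation(strata)
        designs.append(pd.DataFrame(cols))
    return designs


def evaluate_design(runner: Runner, design: pd.DataFrame,
                    outputs: Sequence[str] = OUTPUT_NAMES) -> pd.DataFrame:
    """Run the model for every row of an LHS design."""
    recs = [runner(row._asdict() if hasattr(row, "_asdict") else dict(row))
            for _, row in design.iterrows()]
    return pd.DataFrame(recs)[list(outputs)]


def gsa_mlra(design: pd.DataFrame, output: np.ndarray) -> pd.Series:
    """Standardized multiple-linear-regression coefficients as |SI|."""
    X = _zscore(design.to_numpy(float))
    y = _zscore(np.asarray(output, float).reshape(-1, 1)).ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(np.abs(beta), index=design.columns)


def gsa_prca(design: pd.DataFrame, output: np.ndarray) -> pd.Series:
    """|partial rank correlation| of each parameter with the output."""
    Xr = np.column_stack([stats.rankdata(design[c]) for c in design.columns])
    yr = stats.rankdata(np.asarray(output, float))
    k = Xr.shape[1]
    out = {}
    for j, name in enumerate(design.columns):
        if np.ptp(Xr[:, j]) == 0:
            out[name] = np.nan  # constant column: undefined, flagged as NaN
            continue
        others = np.column_stack(
            [np.ones(len(yr))] + [Xr[:, m] for m in range(k) if m != j]
        )
        rx = Xr[:, j] - others @ np.linalg.lstsq(others, Xr[:, j], rcond=None)[0]
        ry = yr - others @ np.linalg.lstsq(others, yr, rcond=None)[0]
        out[name] = np.abs(np.corrcoef(rx, ry)[0, 1])
    return pd.Series(out)


def gsa_anova(design: pd.DataFrame, output: np.ndarray, n_bins: int = 4) -> pd.Series:
    """One-way ANOVA F of the output across equal-count parameter bins."""
    y = np.asarray(output, float)
    out = {}
    for name in design.columns:
        order = np.argsort(design[name].to_numpy(), kind="stable")
        groups = [y[chunk] for chunk in np.array_split(order, n_bins)]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty ANOVA bin")
        out[name] = stats.f_oneway(*groups).statistic
    return pd.Series(out)


_TECHNIQUES = {"mlra": gsa_mlra, "prca": gsa_prca, "anova": gsa_anova}


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def gsa_weighted_rank(
    si_tables: Dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Merge per-technique replicate SIs into a consensus parameter ranking.

    ``si_tables`` maps technique name to a (replicates × parameters) table of
    |SI| for one model output. Per technique, parameters are ordered by mean
    |SI| across replicates and Tukey-HSD grouping at ``alpha`` assigns tied
    (averaged) ranks to parameters whose replicate SIs are statistically
    indistinguishable. The final rank is the re-ranked equal-weight average
    of the three per-technique ranks.

    Returns (final ranks, per-technique rank table).
    """
    missing = set(_TECHNIQUES) - set(si_tables)
    if missing:
        raise ValueError(f"missing technique results: {sorted(missing)}")
    per_tech = {}
    for tech, table in si_tables.items():
        if len(table) < 2:
            raise ValueError("Tukey grouping needs at least 2 replicates")
        per_tech[tech] = _tukey_grouped_ranks(table, alpha)
    tech_ranks = pd.DataFrame(per_tech)
    mean_rank = tech_ranks.mean(axis=1)
    final = mean_rank.rank(method="average").rename("final_rank")
    return final, tech_ranks


def _tukey_grouped_ranks(table: pd.DataFrame, alpha: float) -> pd.Series:
    """Ranks by mean |SI|, averaging within Tukey-indistinguishable runs."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    means = table.mean(axis=0)
    order = means.sort_values(ascending=False).index.tolist()
    values = table.to_numpy(float).T.ravel()
    labels = np.repeat(table.columns.to_numpy(), len(table))
    if np.allclose(values, values[0]):
        # all SIs identical: everything ties
        return pd.Series((len(order) + 1) / 2.0, index=table.columns)
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    summary = tk.summary().data
    res = pd.DataFrame(summary[1:], columns=summary[0])
    distinct = set()
    for _, row in res.iterrows():
        if bool(row["reject"]):
            distinct.add(frozenset((row["group1"], row["group2"])))

    groups: List[List[str]] = []
    for name in order:
        if groups and all(
            frozenset((name, member)) not in distinct for member in groups[-1]
        ):
            groups[-1].append(name)
        else:
            groups.append([name])
    ranks = {}
    pos = 1
    for g in groups:
        mean_pos = (2 * pos + len(g) - 1) / 2.0
        for name in g:
            ranks[name] = mean_pos
        pos += len(g)
    return pd.Series(ranks).reindex(table.columns)


@dataclass(frozen=True)
class GSAResult:
    """Sensitivity indices and rankings per model output."""

    si: pd.DataFrame            # technique, replicate, output, parameter, si
    final_ranks: pd.DataFrame   # rows parameters, columns outputs
    technique_ranks: Dict[str, pd.DataFrame]
    seed: int
    n: int
    replicates: int


def run_gsa(
    space: ParameterSpace,
    runner: Runner,
    n: int = 5000,
    replicates: int = 10,
    seed: int = 0,
    outputs: Sequence[str] = OUTPUT_NAMES,
    n_bins: int = 4,
) -> GSAResult:
    """Full sampling-based GSA: LHS designs, model runs, three techniques,
    Tukey-grouped per-technique ranks and the equal-weight consensus rank."""
    designs = lhs_sample(space, n=n, replicates=replicates, seed=seed)
    si_rows = []
    tables: Dict[str, Dict[str, List[pd.Series]]] = {
        o: {t: [] for t in _TECHNIQUES} for o in outputs
    }
    for rep, design in enumerate(designs):
        resp = evaluate_design(runner, design, outputs)
        for o in outputs:
            y = resp[o].to_numpy()
            for tech, fn in _TECHNIQUES.items():
                si = fn(design, y, n_bins) if tech == "anova" else fn(design, y)
                tables[o][tech].append(si)
                for name, v in si.items():
                    si_rows.append((tech, rep, o, name, v))
    final = {}
    technique_ranks = {}
    for o in outputs:
        si_tables = {t: pd.DataFrame(tables[o][t]) for t in _TECHNIQUES}
        fr, tr = gsa_weighted_rank(si_tables)
        final[o] = fr
        technique_ranks[o] = tr
    return GSAResult(
        si=pd.DataFrame(si_rows,
                        columns=["technique", "replicate", "output", "parameter", "si"]),
        final_ranks=pd.DataFrame(final).reindex(list(space.names)),
        technique_ranks=technique_ranks,
        seed=seed, n=n, replicates=replicates,
    )
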