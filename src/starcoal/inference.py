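"""Grid-rejection inference of expansion parameters from tree statistics.

A candidate demography is scored by the average normalized delta (AND):
the mean of the three relative absolute deviations between the simulated
and observed tree statistics,

    AND = (|r_s - r_o|/r_o + |m_s - m_o|/m_o + |d_s - d_o|/d_o) / 3,

where each simulated statistic is the average over many replicate
genealogies of the scenario.  The search sweeps a 4-D parameter grid
(start size, end size, expansion end time, expansion duration), excludes
scenarios whose expansion would begin before the haplogroup's TMRCA, and
sequentially narrows the per-axis ranges around the lowest AND values,
and finishes with a mapping round that charts the full extent of the
region scoring below the acceptance cutoff (0.05 by default).  Accepted
cells then yield per-parameter histograms, medians and 95% intervals.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalsim import ExpansionModel, SimConfig, batch_statistics
from .stats import StatVector

__all__ = [
    "PARAM_NAMES",
    "ParamGrid",
    "FitSurface",
    "SearchResult",
    "SearchDivergenceError",
    "and_distance",
    "evaluate_scenario",
    "tmrca_compatible",
    "empirical_tmrca_years",
    "default_grid",
    "evaluate_grid",
    "refine_grid",
    "family_span_grid",
    "fit_observed_tree",
    "sequential_search",
    "summarize",
]

PARAM_NAMES = ("start_n", "end_n", "t_end_years", "duration_years")

AND_CUTOFF = 0.05          # acceptance threshold on the AND value
RETENTION_MARGIN = 1.5     # keep cells with AND <= max(cutoff, round min * margin)
MIN_KEEP = 5               # never narrow based on fewer cells than this


class SearchDivergenceError(RuntimeError):
    """The sequential search could not retain or accept any grid cell."""

    def __init__(self, message, rounds=None):
        super().__init__(message)
        self.rounds = rounds or []


# ---------------------------------------------------------------------------
# Parameter grid
# ---------------------------------------------------------------------------

def _axis(lo: float, hi: float, n: int, spacing: str) -> np.ndarray:
    if hi < lo:
        raise ValueError(f"axis bounds inverted: [{lo}, {hi}]")
    if hi == lo or n == 1:
        return np.array([lo], dtype=float)
    if spacing == "geometric":
        if lo <= 0:
            raise ValueError("geometric axis requires positive lower bound")
        return np.geomspace(lo, hi, n)
    if spacing == "linear":
        return np.linspace(lo, hi, n)
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass(frozen=True)
class ParamGrid:
    """Ordered value lists for the four expansion parameters.

    The Cartesian product of the axes defines the scenarios of one search
    round.  ``spacing`` records how each axis is discretized and
    ``bounds`` the global range refinement may never leave.
    """

    axes: dict
    spacing: dict
    bounds: dict

    def __post_init__(self):
        for p in PARAM_NAMES:
            vals = np.asarray(self.axes[p], dtype=float)
            if vals.size == 0:
                raise ValueError(f"axis {p} is empty")
            if np.any(np.diff(vals) <= 0) and vals.size > 1:
                raise ValueError(f"axis {p} must be strictly increasing")
            object.__setattr__(
                self, "axes", {**self.axes, p: vals}
            )

    @classmethod
    def from_bounds(cls, bounds: dict, spacing: dict, points: int = 5) -> "ParamGrid":
        axes = {
            p: _axis(bounds[p][0], bounds[p][1], points, spacing[p])
            for p in PARAM_NAMES
        }
        return cls(axes=axes, spacing=dict(spacing), bounds=dict(bounds))

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(self.axes[p]) for p in PARAM_NAMES]))

    def cells(self):
        """Yield ``(cell_index, {param: value})`` over the Cartesian product."""
        value_lists = [self.axes[p] for p in PARAM_NAMES]
        for idx, combo in enumerate(itertools.product(*value_lists)):
            yield idx, dict(zip(PARAM_NAMES, combo))


def default_grid(
    max_time_years: float,
    points: int = 5,
    gen_years: float = 30.0,
    overrides: dict | None = None,
) -> ParamGrid:
    """The wide starting grid: sizes on geometric axes, times bounded by
    the haplogroup's empirical TMRCA (expansion end linear from the
    present, duration geometric from one generation)."""
    bounds = {
        "start_n": (1.0, 5000.0),
        "end_n": (100.0, 100000.0),
        "t_end_years": (0.0, max_time_years),
        "duration_years": (gen_years, max_time_years),
    }
    if overrides:
        bounds.update(overrides)
    spacing = {
        "start_n": "geometric",
        "end_n": "geometric",
        "t_end_years": "linear",
        "duration_years": "geometric",
    }
    return ParamGrid.from_bounds(bounds, spacing, points)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def and_distance(sim: StatVector, obs: StatVector) -> float:
    """Average normalized delta between simulated and observed statistics."""
    for name, v in zip(("r", "m", "d"), obs):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"observed statistic {name} must be finite and positive")
    if not sim.is_finite:
        return math.inf
    r_o, m_o, d_o = obs
    r_s, m_s, d_s = sim
    return (abs(r_s - r_o) / r_o + abs(m_s - m_o) / m_o + abs(d_s - d_o) / d_o) / 3.0


def evaluate_scenario(
    model: ExpansionModel,
    obs: StatVector,
    config: SimConfig,
    rng,
    mutate: bool = True,
) -> dict:
    """Score one demographic scenario against the observed statistics.

    Runs ``config.reps`` coalescent replicates, averages each statistic
    component-wise, and returns the AND value of the averaged vector.
    By default the statistics are computed on Poisson SNP-count trees
    (``mutate=True``), matching the observed trees; the SNP clock then
    identifies the absolute scale of sizes and times, which the
    normalized statistics of raw genealogies cannot (they are invariant
    under a joint rescaling).  ``mutate=False`` computes them on the
    genealogy branch lengths instead.

    Replicates whose SNP tree carries no shared variant at all have an
    infinite ``r``; since the observed trees are themselves only
    analysable because they carry shared SNPs, the ``r`` average
    conditions on the same event and such replicates are excluded from
    it (their fraction is reported).  A scenario none of whose
    replicates yields a shared SNP scores ``AND = +inf``.
    """
    res = batch_statistics(model, config, rng, mutate=mutate)
    r_arr, m_arr, d_arr = res["r"], res["m"], res["d"]

    finite = np.isfinite(r_arr)
    frac_inf = 1.0 - finite.mean()
    m_ok = np.isfinite(m_arr)
    mean = StatVector(
        r=float(r_arr[finite].mean()) if finite.any() else math.inf,
        tmrca_mean=float(m_arr[m_ok].mean()) if m_ok.any() else math.nan,
        tmrca_sd=float(d_arr[m_ok].mean()) if m_ok.any() else math.nan,
    )
    if not finite.any() or not m_ok.any():
        and_value = math.inf
    else:
        and_value = and_distance(mean, obs)
    return {"mean": mean, "and": and_value, "frac_inf_r": float(frac_inf)}


def tmrca_compatible(
    model: ExpansionModel, config: SimConfig, max_tmrca_years: float
) -> bool:
    """True iff the expansion begins no earlier than the haplogroup's TMRCA."""
    if max_tmrca_years <= 0:
        raise ValueError("max_tmrca_years must be positive")
    return model.t_end_years + model.duration_years <= max_tmrca_years


def empirical_tmrca_years(tree, config: SimConfig) -> float:
    """TMRCA estimate (years) from mean root-to-tip SNP count.

    Divides the mean root-to-tip count by the expected SNPs per
    generation (mu * seq_len) and scales by the generation time.
    """
    dist = {tree.seed_node: 0.0}
    tips = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            tips.append(dist[node])
    mean_rtt = sum(tips) / len(tips)
    if mean_rtt <= 0:
        raise ValueError("tree has zero root-to-tip length")
    return mean_rtt / config.snps_per_generation * config.gen_years


# ---------------------------------------------------------------------------
# Grid evaluation and sequential refinement
# ---------------------------------------------------------------------------

@dataclass
class FitSurface:
    """AND values over one round's grid, as a long-format table."""

    table: pd.DataFrame  # one row per cell
    round_index: int = 0

    @property
    def evaluated(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]

    @property
    def accepted(self) -> pd.DataFrame:
        ev = self.evaluated
        return ev[ev["and_value"] < AND_CUTOFF]

    def to_tsv(self, path) -> None:
        cols = [
            "start_n", "end_n", "t_end_years", "duration_years",
            "r_s", "m_s", "d_s", "and_value", "excluded",
        ]
        self.table[cols].to_csv(path, sep="\t", index=False)


def _cell_rng(seed: int, round_index: int, cell_index: int):
    ss = np.random.SeedSequence([int(seed) % (2**31), round_index, cell_index])
    return np.random.default_rng(ss)


def evaluate_grid(
    grid: ParamGrid,
    obs: StatVector,
    config: SimConfig,
    max_tmrca_years: float,
    seed: int | None = None,
    round_index: int = 0,
    mutate: bool = True,
) -> FitSurface:
    """Score every grid cell; cells violating the TMRCA bound are excluded
    before simulation.  Deterministic given ``seed`` (per-cell RNG streams
    derive from (seed, round, cell))."""
    if seed is None:
        seed = config.seed
    rows = []
    for idx, params in grid.cells():
        model = ExpansionModel(**params)
        row = dict(params)
        row["cell"] = idx
        if not tmrca_compatible(model, config, max_tmrca_years):
            row.update(
                r_s=np.nan, m_s=np.nan, d_s=np.nan, and_value=np.nan,
                frac_inf_r=np.nan, excluded=True,
                reason="expansion predates haplogroup TMRCA",
            )
        else:
            rng = _cell_rng(seed, round_index, idx)
            res = evaluate_scenario(model, obs, config, rng, mutate=mutate)
            row.update(
                r_s=res["mean"].r, m_s=res["mean"].tmrca_mean,
                d_s=res["mean"].tmrca_sd, and_value=res["and"],
                frac_inf_r=res["frac_inf_r"], excluded=False, reason="",
            )
        rows.append(row)
    return FitSurface(table=pd.DataFrame(rows), round_index=round_index)


def _axis_step_down(v: float, values: np.ndarray, spacing: str) -> float:
    if spacing == "geometric":
        ratio = (values[-1] / values[0]) ** (1.0 / (len(values) - 1)) if len(values) > 1 else 2.0
        return v / ratio
    step = (values[-1] - values[0]) / (len(values) - 1) if len(values) > 1 else max(abs(v) * 0.5, 1.0)
    return v - step


def _axis_step_up(v: float, values: np.ndarray, spacing: str) -> float:
    if spacing == "geometric":
        ratio = (values[-1] / values[0]) ** (1.0 / (len(values) - 1)) if len(values) > 1 else 2.0
        return v * ratio
    step = (values[-1] - values[0]) / (len(values) - 1) if len(values) > 1 else max(abs(v) * 0.5, 1.0)
    return v + step


def refine_grid(
    surface: FitSurface,
    grid: ParamGrid,
    cutoff: float = AND_CUTOFF,
    margin: float = RETENTION_MARGIN,
    min_keep: int = MIN_KEEP,
    points: int = 5,
    contraction: float = 0.8,
) -> ParamGrid:
    """Narrow the grid around the best-fitting cells.

    A conservative selection keeps every cell with AND no larger than
    ``max(cutoff, round minimum * margin)`` and never fewer than
    ``min_keep`` cells.  Each new axis range spans the kept values
    extended by one grid step on either side, clipped to the global
    bounds, then re-discretized at ``points`` values.

    Because the well-fitting region is typically a curved ridge in the
    4-D space, the bounding box of the kept cells alone can fail to
    shrink; each axis is therefore additionally required to contract to
    at most ``contraction`` times its previous width (measured in log
    units on geometric axes), recentred on the inverse-AND-weighted mean
    of the kept cells.  This guarantees the search resolves the basin
    floor at a geometric rate while earlier, wider rounds have already
    charted the full extent of the fitting region.  Set
    ``contraction=1`` to disable the guarantee and use the plain
    bounding-box rule.
    """
    ev = surface.evaluated
    ev = ev[np.isfinite(ev["and_value"])]
    if len(ev) == 0:
        raise SearchDivergenceError("no evaluated cells with finite AND to refine on")
    best = ev["and_value"].min()
    keep = ev[ev["and_value"] <= max(cutoff, best * margin)]
    if len(keep) < min_keep:
        keep = ev.nsmallest(min(min_keep, len(ev)), "and_value")
    weights = 1.0 / np.maximum(keep["and_value"].to_numpy(), 1e-4) ** 2
    weights = weights / weights.sum()
    axes = {}
    for p in PARAM_NAMES:
        vals = grid.axes[p]
        spacing = grid.spacing[p]
        lo_b, hi_b = grid.bounds[p]
        lo = _axis_step_down(float(keep[p].min()), vals, spacing)
        hi = _axis_step_up(float(keep[p].max()), vals, spacing)
        lo = min(max(lo, lo_b), hi_b)
        hi = max(min(hi, hi_b), lo_b)
        if hi < lo:
            lo, hi = hi, lo
        kv = keep[p].to_numpy(dtype=float)
        if spacing == "geometric":
            old_w = math.log(vals[-1] / vals[0]) if len(vals) > 1 else 0.0
            new_w = math.log(hi / lo) if hi > lo else 0.0
            max_w = contraction * old_w
            if new_w > max_w > 0:
                centre = math.exp(float(np.sum(weights * np.log(kv))))
                lo = centre * math.exp(-max_w / 2)
                hi = centre * math.exp(max_w / 2)
                lo = min(max(lo, lo_b), hi_b)
                hi = max(min(hi, hi_b), lo_b)
        else:
            old_w = vals[-1] - vals[0] if len(vals) > 1 else 0.0
            new_w = hi - lo
            max_w = contraction * old_w
            if new_w > max_w > 0:
                centre = float(np.sum(weights * kv))
                lo = min(max(centre - max_w / 2, lo_b), hi_b)
                hi = max(min(centre + max_w / 2, hi_b), lo_b)
        axes[p] = _axis(lo, hi, points, spacing)
    return ParamGrid(axes=axes, spacing=dict(grid.spacing), bounds=dict(grid.bounds))


def family_span_grid(
    cells: pd.DataFrame,
    grid: ParamGrid,
    max_tmrca_years: float,
    points: int = 7,
    time_points: int = 9,
) -> ParamGrid:
    """Grid spanning the scale-degenerate family through the given cells.

    The three normalized tree statistics are exactly invariant under a
    joint rescaling of all population sizes and times by a factor ``c``
    (the coalescent clock runs ``c`` times slower in a ``c``-times larger
    population), so every well-fitting scenario belongs to a
    one-parameter family of equally well-fitting scenarios, clipped only
    by the global parameter bounds and by the requirement that the
    expansion begin no earlier than the haplogroup's TMRCA.  This builds
    the axis-aligned envelope of those families for a set of retained
    cells — the final mapping round of the search evaluates it so the
    accepted region (and hence the parameter histograms) reflects the
    full extent of the fitting region rather than the arbitrary scale at
    which the zoom rounds happened to resolve it.
    """
    lo = {p: math.inf for p in PARAM_NAMES}
    hi = {p: -math.inf for p in PARAM_NAMES}
    for _, row in cells.iterrows():
        onset = row["t_end_years"] + row["duration_years"]
        c_lo = max(
            grid.bounds["start_n"][0] / row["start_n"],
            grid.bounds["end_n"][0] / row["end_n"],
            grid.bounds["duration_years"][0] / max(row["duration_years"], 1e-9),
        )
        c_hi = min(
            grid.bounds["start_n"][1] / row["start_n"],
            grid.bounds["end_n"][1] / row["end_n"],
            max_tmrca_years / max(onset, 1e-9),
        )
        c_hi = max(c_hi, c_lo)
        for p in PARAM_NAMES:
            lo[p] = min(lo[p], row[p] * c_lo)
            hi[p] = max(hi[p], row[p] * c_hi)
    axes = {}
    spacing = dict(grid.spacing)
    for p in PARAM_NAMES:
        lo_b, hi_b = grid.bounds[p]
        a = min(max(lo[p], lo_b), hi_b)
        b = max(min(hi[p], hi_b), lo_b)
        if b < a:
            a, b = b, a
        if p in ("t_end_years", "duration_years"):
            # Mapping wants even coverage of the fitting region's extent;
            # the time axes are therefore sampled linearly and more
            # finely here, whereas the zoom rounds use the grid's own
            # (possibly geometric) spacing to locate the scale.
            spacing[p] = "linear"
            axes[p] = _axis(a, b, time_points, "linear")
        else:
            axes[p] = _axis(a, b, points, grid.spacing[p])
    return ParamGrid(axes=axes, spacing=spacing, bounds=dict(grid.bounds))


# ---------------------------------------------------------------------------
# Sequential search
# ---------------------------------------------------------------------------

@dataclass
class RoundRecord:
    grid: ParamGrid
    surface: FitSurface
    accepted_fraction: float


@dataclass
class SearchResult:
    """Full history of a sequential grid search plus best-fit summaries.

    ``accepted_mode`` is ``"absolute"`` when the accepted set consists of
    scenarios with AND below the cutoff, and ``"relative"`` when no
    scenario ever reached the cutoff and the set instead holds the
    conservative selection of the lowest AND values explored (within
    :data:`RETENTION_MARGIN` of the global minimum).  Relative fits say
    only that these are the best fits among the ranges explored, not
    that the model fits the data in absolute terms.
    """

    rounds: list
    accepted: pd.DataFrame
    summaries: dict
    converged: bool
    accepted_mode: str = "absolute"

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def to_json(self, path=None) -> str:
        payload = {
            "n_rounds": self.n_rounds,
            "converged": self.converged,
            "accepted_fraction_per_round": [r.accepted_fraction for r in self.rounds],
            "accepted_cells": self.accepted[list(PARAM_NAMES) + ["and_value"]].to_dict(
                orient="records"
            ),
            "summaries": self.summaries,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_observed_tree(
    tree,
    config: SimConfig,
    seed: int | None = None,
    max_rounds: int = 12,
    cutoff: float = AND_CUTOFF,
    max_tmrca_years: float | None = None,
    grid: ParamGrid | None = None,
    mutate: bool = True,
    progress=None,
) -> SearchResult:
    """End-to-end fit of the expansion model to an observed SNP tree.

    Computes the observed statistics and the SNP-clock TMRCA, builds the
    default wide starting grid (unless one is supplied) and runs the
    sequential search.  ``max_tmrca_years`` defaults to the tree's own
    empirical TMRCA; pass an external estimate to relax or tighten the
    compatibility bound.
    """
    from .stats import stat_vector

    obs = stat_vector(tree)
    emp = empirical_tmrca_years(tree, config)
    if max_tmrca_years is None:
        max_tmrca_years = emp
    if grid is None:
        grid = default_grid(max_tmrca_years, gen_years=config.gen_years)
    return sequential_search(
        obs, grid, config, max_tmrca_years, cutoff=cutoff,
        max_rounds=max_rounds, seed=seed, mutate=mutate, progress=progress,
    )


def summarize(accepted: pd.DataFrame) -> dict:
    """Per-parameter histogram, median and 2.5-97.5 percentile interval
    over the accepted cells (each cell counts once)."""
    if len(accepted) == 0:
        raise ValueError("no accepted cells to summarize")
    out = {}
    for p in PARAM_NAMES:
        vals = np.asarray(accepted[p], dtype=float)
        uniq, counts = np.unique(vals, return_counts=True)
        out[p] = {
            "median": float(np.median(vals)),
            "ci_low": float(np.percentile(vals, 2.5)),
            "ci_high": float(np.percentile(vals, 97.5)),
            "histogram": {float(v): int(c) for v, c in zip(uniq, counts)},
        }
    return out


def sequential_search(
    obs: StatVector,
    initial: ParamGrid,
    config: SimConfig,
    max_tmrca_years: float,
    cutoff: float = AND_CUTOFF,
    stop_fraction: float = 0.5,
    max_rounds: int = 12,
    seed: int | None = None,
    mutate: bool = True,
    progress=None,
) -> SearchResult:
    """Zoom onto the best-fitting region, then map its full extent.

    The first ``max_rounds - 1`` rounds progressively narrow the grid
    around the lowest AND values (stopping early if at least
    ``stop_fraction`` of a round's evaluated cells already score below
    ``cutoff``).  The final round then evaluates a wide mapping grid
    spanning the scale-degenerate family of every retained fit (see
    :func:`family_span_grid`); its sub-``cutoff`` cells form the
    accepted set, so the per-parameter histograms reflect the whole
    well-fitting region, clipped by the global bounds and the TMRCA
    constraint.  If no scenario in any round reaches the absolute
    cutoff, the accepted set falls back to the conservative selection of
    the lowest AND values explored (``accepted_mode="relative"``).
    Raises :class:`SearchDivergenceError` (with the round history
    attached) if nothing can be evaluated at all.
    """
    if seed is None:
        seed = config.seed
    grid = initial
    rounds: list[RoundRecord] = []

    def _do_round(g, rnd):
        surface = evaluate_grid(
            g, obs, config, max_tmrca_years, seed=seed, round_index=rnd,
            mutate=mutate,
        )
        ev = surface.evaluated
        n_eval = int(np.isfinite(ev["and_value"]).sum())
        if n_eval == 0:
            raise SearchDivergenceError(
                f"round {rnd}: every grid cell excluded or degenerate", rounds
            )
        frac = float((ev["and_value"] < cutoff).sum()) / n_eval
        rounds.append(RoundRecord(grid=g, surface=surface, accepted_fraction=frac))
        if progress is not None:
            progress(rnd, frac, float(np.nanmin(ev["and_value"])))
        return frac

    for rnd in range(max_rounds - 1):
        frac = _do_round(grid, rnd)
        if frac >= stop_fraction:
            break
        if rnd < max_rounds - 2:
            try:
                grid = refine_grid(surface=rounds[-1].surface, grid=grid, cutoff=cutoff)
            except SearchDivergenceError as exc:
                exc.rounds = rounds
                raise

    def _pool(recs):
        parts = []
        for rec in recs:
            ev = rec.surface.evaluated
            ev = ev[np.isfinite(ev["and_value"])]
            if len(ev):
                ev = ev.copy()
                ev["round"] = rec.surface.round_index
                parts.append(ev)
        if not parts:
            raise SearchDivergenceError("no evaluated cells in any round", recs)
        return pd.concat(parts, ignore_index=True)

    zoom_pool = _pool(rounds)
    best = float(zoom_pool["and_value"].min())
    retained = zoom_pool[
        zoom_pool["and_value"] <= max(cutoff, best * RETENTION_MARGIN)
    ]
    map_grid = family_span_grid(retained, grid, max_tmrca_years)
    _do_round(map_grid, len(rounds))

    final = rounds[-1].surface.evaluated
    final = final[np.isfinite(final["and_value"])].copy()
    final["round"] = rounds[-1].surface.round_index
    accepted = final[final["and_value"] < cutoff].copy()
    mode = "absolute"
    if len(accepted) == 0:
        pool = _pool(rounds)
        accepted = pool[pool["and_value"] < cutoff].copy()
        if len(accepted) == 0:
            # nothing met the absolute cutoff anywhere: report the
            # conservative selection of the lowest AND values on the
            # mapping round (falling back to the whole exploration if
            # the mapping round somehow missed the optimum)
            mode = "relative"
            global_min = float(pool["and_value"].min())
            accepted = final[
                final["and_value"] <= global_min * RETENTION_MARGIN
            ].copy()
            if len(accepted) == 0:
                accepted = pool[
                    pool["and_value"] <= global_min * RETENTION_MARGIN
                ].copy()
    return SearchResult(
        rounds=rounds,
        accepted=accepted,
        summaries=summarize(accepted),
        converged=rounds[-1].accepted_fraction >= stop_fraction,
        accepted_mode=mode,
    )
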