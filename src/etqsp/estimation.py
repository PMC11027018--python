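"""Objective computation, bounded least squares, and mechanism selection.

Calibration minimizes the weighted sum of squared residuals (OBJ) between
simulated and observed study time courses.  Residuals are weighted by the
reported standard error where one is available and by 5% of the variable's
baseline value otherwise, which puts mmHg-, L/min- and percent-scale
variables on comparable footing when several studies are fitted jointly.

Mechanism identification is greedy forward selection: starting from a NULL
model with no ET-1 effects, every remaining candidate arm (receptor x target
x functional form) is added in turn, all retained slopes are re-fitted
jointly, and the arm giving the largest OBJ reduction is kept; rounds stop
when the best reduction fails the stop rule (default: at least a 1% relative
drop, and larger than the spread across multi-start replicates).  A backward
elimination pass then drops each retained arm in turn and flags any whose
removal does not worsen the objective.  At equal objective, a linear form is
preferred over a sigmoidal one (fewer parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .coupled import CoupledModel
from .effects import MechanismSpec
from .kinetics import SimulationError
from .cardiorenal import ModelOutputs
from .protocols import Protocol, ALL_STUDIES

log = logging.getLogger(__name__)

OBS_COLUMNS = ["study", "arm", "variable", "time", "bin_start", "bin_end",
               "value", "se", "n_subjects"]


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Schema check for an observation table; returns the table unchanged."""
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table lacks columns {missing}")
    bad = set(obs["variable"]) - set(ModelOutputs.VARIABLES)
    if bad:
        raise ValueError(f"unknown observation variables {sorted(bad)}")
    se = obs["se"].to_numpy(dtype=float)
    if np.any(se[np.isfinite(se)] <= 0):
        raise ValueError("standard errors must be positive where provided")
    return obs


@dataclass
class FitResult:
    """Outcome of one bounded least-squares calibration."""

    mechanisms: list[MechanismSpec]
    OBJ: float
    se_pct: dict[tuple, float]        # parameter -> SE as % of estimate
    n_obs: int
    at_bounds: list[tuple] = field(default_factory=list)
    start_objs: list[float] = field(default_factory=list)
    success: bool = True
    message: str = ""

    @property
    def params(self) -> dict[tuple, float]:
        out = {}
        for m in self.mechanisms:
            out[m.key + ("m",)] = m.m
            if m.form == "sigmoidal":
                out[m.key + ("b",)] = m.b
        return out

    @property
    def multistart_spread(self) -> float:
        finite = [o for o in self.start_objs if np.isfinite(o)]
        return (max(finite) - min(finite)) if len(finite) > 1 else 0.0


class Objective:
    """Weighted least-squares objective over one or more studies.

    The coupled model is simulated once per study arm per evaluation; the
    kinetic stage is cached inside the model, so the marginal cost is the
    cardiorenal solve.
    """

    def __init__(self, model: CoupledModel, observations: pd.DataFrame,
                 protocols: dict[tuple[str, str], Protocol] | None = None):
        observations = validate_observations(observations).reset_index(drop=True)
        self.model = model
        self.observations = observations
        if protocols is None:
            protocols = model.protocol_registry(ALL_STUDIES)
        self.protocols = protocols
        self._groups: list[tuple[Protocol, pd.DataFrame]] = []
        for (study, arm), grp in observations.groupby(["study", "arm"],
                                                      sort=True):
            key = (study, arm)
            if key not in protocols:
                raise ValueError(f"no protocol registered for {key}")
            self._groups.append((protocols[key], grp))
        self._weights = self._build_weights()
        self._plans = [self._build_plan(protocol, grp)
                       for protocol, grp in self._groups]
        self.n_obs = len(observations)
        self.n_failures = 0

    def _baseline_value(self, protocol: Protocol, variable: str) -> float:
        out = self.model.run(protocol, mechanisms=[])
        v = np.interp(0.0, out.time, out[variable])
        return float(v)

    def _build_weights(self) -> list[np.ndarray]:
        weights = []
        for protocol, grp in self._groups:
            se = grp["se"].to_numpy(dtype=float)
            w = se.copy()
            fallback = ~np.isfinite(se)
            if fallback.any():
                for var in grp.loc[fallback, "variable"].unique():
                    base = abs(self._baseline_value(protocol, var))
                    rows = fallback & (grp["variable"] == var).to_numpy()
                    w[rows] = max(0.05 * base, 1e-9)
            weights.append(w)
        return weights

    #: weighted-residual magnitude assigned to undefined predictions (e.g.
    #: FENa while filtration is clamped at zero); large enough to repel the
    #: optimizer, finite enough to keep it alive
    UNDEFINED_PENALTY = 1e3

    def _build_plan(self, protocol: Protocol, grp: pd.DataFrame):
        """Precompile per-row extraction against the protocol's schedule.

        The simulation grid is deterministic per protocol, so instantaneous
        samples reduce to interpolation at fixed times and collection bins to
        trapezoids over fixed index ranges; validating the schedule here lets
        each objective evaluation stay purely numeric.
        """
        t_grid = self.model._time_grid(protocol)
        plan = []
        for _, row in grp.iterrows():
            var, tm = row["variable"], float(row["time"])
            a = row.get("bin_start", np.nan)
            if np.isfinite(a):
                a, b = float(a), float(row["bin_end"])
                if (a, b) not in protocol.urine_bins:
                    raise ValueError(
                        f"observation bin ({a}, {b}) for {var} not in "
                        f"{protocol.label}'s collection schedule")
                mask = (t_grid >= a - 1e-9) & (t_grid <= b + 1e-9)
                plan.append((var, mask, None))
            else:
                if tm < t_grid[0] or tm > t_grid[-1]:
                    raise ValueError(
                        f"observation time {tm} for {var} outside "
                        f"{protocol.label}'s simulation span")
                plan.append((var, None, tm))
        return t_grid, plan

    def residuals(self, mechanisms: list[MechanismSpec]) -> np.ndarray:
        """Weighted residual vector (sim - obs)/w across all observations."""
        res = []
        for (protocol, grp), w, (t_grid, plan) in zip(
                self._groups, self._weights, self._plans):
            out = self.model.run(protocol, mechanisms)
            sim = np.empty(len(plan))
            series_cache: dict[str, np.ndarray] = {}
            for i, (var, mask, tm) in enumerate(plan):
                series = series_cache.get(var)
                if series is None:
                    series = out[var]
                    series_cache[var] = series
                if mask is None:
                    sim[i] = np.interp(tm, out.time, series)
                else:
                    tt = out.time[mask]
                    sim[i] = np.trapezoid(series[mask], tt) / (tt[-1] - tt[0])
            r = (sim - grp["value"].to_numpy(dtype=float)) / w
            # undefined model predictions (clamped GFR makes FENa missing)
            # penalize the trial point instead of aborting the fit
            r[~np.isfinite(r)] = self.UNDEFINED_PENALTY
            res.append(r)
        return np.concatenate(res)

    def __call__(self, mechanisms: list[MechanismSpec]) -> float:
        """OBJ = sum of squared weighted residuals; +inf if simulation fails."""
        try:
            r = self.residuals(mechanisms)
        except SimulationError as exc:
            self.n_failures += 1
            log.warning("simulation failure during objective: %s", exc)
            return np.inf
        return float(r @ r)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

DEFAULT_M_BOUNDS = (-10.0, 10.0)
DEFAULT_B_BOUNDS = (1e-2, 1e2)


def _pack(mechanisms):
    """Parameter vector layout: m for each arm, then b for sigmoidal arms."""
    x, lo, hi, labels = [], [], [], []
    for m in mechanisms:
        x.append(m.m)
        lo.append(DEFAULT_M_BOUNDS[0])
        hi.append(DEFAULT_M_BOUNDS[1])
        labels.append(m.key + ("m",))
    for m in mechanisms:
        if m.form == "sigmoidal":
            x.append(m.b)
            lo.append(DEFAULT_B_BOUNDS[0])
            hi.append(DEFAULT_B_BOUNDS[1])
            labels.append(m.key + ("b",))
    return np.array(x), np.array(lo), np.array(hi), labels


def _unpack(mechanisms, x):
    out = []
    i = 0
    for m in mechanisms:
        out.append(m.with_params(float(x[i])))
        i += 1
    j = i
    for k, m in enumerate(out):
        if m.form == "sigmoidal":
            out[k] = m.with_params(m.m, float(x[j]))
            j += 1
    return out


def fit_parameters(model: CoupledModel,
                   mechanisms: list[MechanismSpec],
                   observations: pd.DataFrame | Objective,
                   bounds: tuple[np.ndarray, np.ndarray] | None = None,
                   start: np.ndarray | None = None,
                   n_starts: int = 5,
                   seed: int = 0,
                   jitter: float = 0.3,
                   ftol: float = 1e-8,
                   xtol: float = 1e-10,
                   diff_step: float = 3e-3,
                   max_nfev: int | None = None) -> FitResult:
    """Bounded trust-region least squares with seeded multi-start.

    The first start is ``start`` (default: the slopes currently stored on
    ``mechanisms``); the remaining starts jitter it with seeded Gaussian
    perturbations of scale ``jitter * (1 + |x|)``.  Standard errors come
    from the Jacobian at the optimum (Gauss-Newton covariance) and are
    reported as percent of each estimate.
    """
    obj = (observations if isinstance(observations, Objective)
           else Objective(model, observations))
    x0, lo, hi, labels = _pack(mechanisms)
    if bounds is not None:
        lo, hi = np.broadcast_to(bounds[0], lo.shape), np.broadcast_to(
            bounds[1], hi.shape)
    if start is not None:
        x0 = np.asarray(start, dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("start point outside bounds")

    def resid(x):
        try:
            return obj.residuals(_unpack(mechanisms, x))
        except SimulationError:
            obj.n_failures += 1
            return np.full(obj.n_obs, 1e6)

    rng = np.random.default_rng(seed)
    best = None
    start_objs = []
    errors = []
    fallback = None   # (obj, x) when the optimizer cannot take any step
    for s in range(max(n_starts, 1)):
        xs = x0.copy()
        if s > 0:
            xs = np.clip(x0 + rng.normal(0, jitter * (1 + np.abs(x0))), lo, hi)
        try:
            # finite-difference steps must sit well above the ODE solver's
            # noise floor or the trust region collapses prematurely; an
            # explicit x_scale keeps candidates with (numerically) inert
            # parameters from crashing the Jacobian-based autoscaling
            sol = least_squares(resid, xs, bounds=(lo, hi), method="trf",
                                ftol=ftol, xtol=xtol,
                                x_scale=np.maximum(np.abs(xs), 0.1),
                                diff_step=diff_step, max_nfev=max_nfev)
        except ZeroDivisionError:
            # a parameter with no influence on any residual (e.g. a venous
            # arm while blood volume sits at baseline) leaves TRF without a
            # predicted reduction; score the start point itself instead
            r = resid(xs)
            obj_here = float(r @ r)
            start_objs.append(obj_here)
            if fallback is None or obj_here < fallback[0]:
                fallback = (obj_here, xs.copy())
            continue
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(f"start {s}: {exc}")
            start_objs.append(np.inf)
            continue
        start_objs.append(2.0 * sol.cost)
        if best is None or 2.0 * sol.cost < 2.0 * best.cost:
            best = sol
    if best is None and fallback is not None:
        return FitResult(mechanisms=_unpack(mechanisms, fallback[1]),
                         OBJ=fallback[0],
                         se_pct={lab: np.inf for lab in labels},
                         n_obs=obj.n_obs, start_objs=start_objs,
                         success=True,
                         message="no identifiable improvement direction")
    if best is None:
        raise SimulationError(
            "all optimizer starts failed: " + "; ".join(errors))

    fitted = _unpack(mechanisms, best.x)
    # Gauss-Newton covariance; weights are the observation SEs, so no
    # residual-variance rescaling is applied
    J = best.jac
    se_pct = {}
    try:
        cov = np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        for lab, s_, v in zip(labels, se, best.x):
            se_pct[lab] = float(100.0 * s_ / abs(v)) if v != 0 else np.inf
    except np.linalg.LinAlgError:
        se_pct = {lab: np.nan for lab in labels}
    at_bounds = [lab for lab, v, l, h in zip(labels, best.x, lo, hi)
                 if np.isclose(v, l) or np.isclose(v, h)]
    return FitResult(mechanisms=fitted, OBJ=float(2.0 * best.cost),
                     se_pct=se_pct, n_obs=obj.n_obs, at_bounds=at_bounds,
                     start_objs=start_objs, success=True,
                     message=best.message)


# ---------------------------------------------------------------------------
# forward selection / backward elimination
# ---------------------------------------------------------------------------

@dataclass
class StopRule:
    """Round acceptance rule for forward selection."""

    rel_reduction: float = 0.01   # minimum relative OBJ drop to accept
    #: OBJ values within this relative band are treated as equal, and the
    #: candidate with fewer parameters wins -- a sigmoidal form is only
    #: chosen over a linear one if it improves OBJ beyond the same 1%
    #: resolution that defines a meaningful round
    tie_rel: float = 0.01

    def accepts(self, prev_obj: float, new_obj: float, spread: float) -> bool:
        drop = prev_obj - new_obj
        return drop >= self.rel_reduction * prev_obj and drop > spread


@dataclass
class CandidateRecord:
    receptor: str
    target: str
    form: str
    OBJ: float
    fitted_m: float
    fitted_b: float | None = None


@dataclass
class SelectionRound:
    round_index: int
    candidates: list[CandidateRecord]
    winner: MechanismSpec | None
    OBJ: float
    pct_from_null: float
    pct_from_prev: float
    accepted: bool


@dataclass
class SelectionTrace:
    """Full record of a forward-selection / backward-elimination run."""

    null_obj: float
    rounds: list[SelectionRound] = field(default_factory=list)
    selected: list[MechanismSpec] = field(default_factory=list)
    final_obj: float = np.nan
    backward: list[tuple[tuple, float, bool]] = field(default_factory=list)
    #: mechanisms flagged as removable by backward elimination
    flagged: list[tuple] = field(default_factory=list)

    def accepted_objs(self) -> list[float]:
        return [r.OBJ for r in self.rounds if r.accepted]

    def final_mechanisms(self) -> list[MechanismSpec]:
        """Selected arms surviving backward elimination."""
        return [m for m in self.selected if m.key not in self.flagged]

    def selected_keys(self) -> set[tuple]:
        return {m.key for m in self.selected}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rounds:
            for c in r.candidates:
                rows.append({
                    "round": r.round_index, "receptor": c.receptor,
                    "target": c.target, "form": c.form, "OBJ": c.OBJ,
                    "m": c.fitted_m, "b": c.fitted_b,
                    "winner": (r.winner is not None and r.accepted
                               and (c.receptor, c.target) == r.winner.key
                               and c.form == r.winner.form),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"NULL OBJ = {self.null_obj:.4g}"]
        for r in self.rounds:
            if r.accepted and r.winner is not None:
                lines.append(
                    f"round {r.round_index}: + {r.winner.receptor}->"
                    f"{r.winner.target} ({r.winner.form}) OBJ={r.OBJ:.4g} "
                    f"({r.pct_from_null:+.1f}% vs NULL, "
                    f"{r.pct_from_prev:+.1f}% vs prev)")
            else:
                lines.append(
                    f"round {r.round_index}: no candidate passed the stop "
                    f"rule; selection stops")
        for key, obj_drop, flagged in self.backward:
            mark = " [flagged removable]" if flagged else ""
            lines.append(f"backward: - {key[0]}->{key[1]} OBJ={obj_drop:.4g}"
                         f"{mark}")
        return "\n".join(lines)


def forward_select(model: CoupledModel,
                   candidates: list[MechanismSpec],
                   observations: pd.DataFrame | Objective,
                   stop_rule: StopRule | None = None,
                   n_starts: int = 1,
                   seed: int = 0,
                   max_rounds: int | None = None,
                   refit_all: bool = True,
                   ftol: float = 1e-6) -> SelectionTrace:
    """Greedy forward selection of mechanism arms.

    Each round jointly refits every retained slope together with the new
    candidate (``refit_all=True``, the default; ``False`` freezes previously
    accepted slopes, for comparison).  Returns the full per-round trace.
    """
    stop_rule = stop_rule or StopRule()
    obj = (observations if isinstance(observations, Objective)
           else Objective(model, observations))
    null_obj = obj([])
    trace = SelectionTrace(null_obj=null_obj)
    kept: list[MechanismSpec] = []
    prev_obj = null_obj
    remaining = list(candidates)
    if max_rounds is None:
        max_rounds = len({c.key for c in candidates}) + 1
    rng = np.random.default_rng(seed)

    for rnd in range(1, max_rounds + 1):
        remaining = [c for c in remaining
                     if c.key not in {k.key for k in kept}]
        if not remaining:
            break
        records = []
        best = None   # (OBJ, n_params, order, fitted mechs, candidate, fit)
        for order, cand in enumerate(remaining):
            try:
                if refit_all:
                    trial = kept + [cand]
                    # cold start: all slopes from zero. Greedy warm starts
                    # can lock the joint refit into the previous round's
                    # local minimum; this landscape converges reliably from
                    # the origin
                    start = np.array([0.0] * len(trial)
                                     + [m.b for m in trial
                                        if m.form == "sigmoidal"])
                    cap = 30 + 15 * len(start)
                    fit = fit_parameters(model, trial, obj, start=start,
                                         n_starts=n_starts, ftol=ftol,
                                         max_nfev=cap,
                                         seed=int(rng.integers(2**31 - 1)))
                    fitted, obj_val = fit.mechanisms, fit.OBJ
                else:
                    frozen = [replace(c) for c in kept]
                    fit = fit_parameters(model, [cand],
                                         _FrozenObjective(obj, frozen),
                                         n_starts=n_starts, ftol=ftol,
                                         max_nfev=60,
                                         seed=int(rng.integers(2**31 - 1)))
                    fitted, obj_val = frozen + fit.mechanisms, fit.OBJ
            except SimulationError as exc:
                log.warning("candidate %s (%s) failed to fit: %s",
                            cand.key, cand.form, exc)
                records.append(CandidateRecord(cand.receptor, cand.target,
                                               cand.form, np.inf, np.nan))
                continue
            new_mech = fitted[-1]
            records.append(CandidateRecord(
                cand.receptor, cand.target, cand.form, obj_val, new_mech.m,
                new_mech.b if cand.form == "sigmoidal" else None))
            n_par = sum(m.n_params for m in fitted)
            # strictly better OBJ wins; within the tie tolerance prefer
            # fewer parameters (linear over sigmoidal), then earlier order
            if best is None:
                best = (obj_val, n_par, order, fitted, cand, fit)
            else:
                tie = abs(obj_val - best[0]) <= stop_rule.tie_rel * max(
                    best[0], 1e-30)
                better = (tie and (n_par, order) < (best[1], best[2])) or (
                    not tie and obj_val < best[0])
                if better:
                    best = (obj_val, n_par, order, fitted, cand, fit)
        obj_val, _, _, fitted, cand, fit = best
        accepted = stop_rule.accepts(prev_obj, obj_val, fit.multistart_spread)
        log.info("selection round %d: best %s->%s (%s) OBJ %.4g (%saccepted)",
                 rnd, cand.receptor, cand.target, cand.form, obj_val,
                 "" if accepted else "not ")
        winner = fitted[-1] if accepted else None

        def _pct(new, ref):
            if ref == 0.0:
                return 0.0 if new == 0.0 else np.inf
            return 100.0 * (new - ref) / ref

        trace.rounds.append(SelectionRound(
            round_index=rnd, candidates=records, winner=winner,
            OBJ=obj_val if accepted else prev_obj,
            pct_from_null=_pct(obj_val, null_obj),
            pct_from_prev=_pct(obj_val, prev_obj),
            accepted=accepted))
        if not accepted:
            break
        kept = fitted
        prev_obj = obj_val
        remaining = [c for c in remaining if c.key != cand.key]

    trace.selected = kept
    trace.final_obj = prev_obj
    return trace


class _FrozenObjective(Objective):
    """Objective wrapper that appends frozen mechanisms to each evaluation."""

    def __init__(self, base: Objective, frozen: list[MechanismSpec]):
        # share caches/groups with the base objective; no re-validation
        self.__dict__.update(base.__dict__)
        self._frozen = frozen

    def residuals(self, mechanisms):
        return Objective.residuals(self, self._frozen + list(mechanisms))


def backward_eliminate(model: CoupledModel,
                       selected: list[MechanismSpec],
                       observations: pd.DataFrame | Objective,
                       stop_rule: StopRule | None = None,
                       n_starts: int = 1,
                       seed: int = 0,
                       trace: SelectionTrace | None = None,
                       ftol: float = 1e-6) -> SelectionTrace:
    """Drop-one confirmation of a selected mechanism set.

    For each retained arm the remaining slopes are refitted without it; arms
    whose removal does not increase the objective beyond the stop-rule
    tolerance are flagged as removable.
    """
    if not selected:
        raise ValueError("backward elimination needs a non-empty selection")
    stop_rule = stop_rule or StopRule()
    obj = (observations if isinstance(observations, Objective)
           else Objective(model, observations))
    full_obj = obj(selected)
    if trace is None:
        trace = SelectionTrace(null_obj=obj([]))
        trace.selected = list(selected)
    trace.final_obj = full_obj
    rng = np.random.default_rng(seed)
    for i, mech in enumerate(selected):
        rest = [m for j, m in enumerate(selected) if j != i]
        if rest:
            fit = fit_parameters(model, rest,
                                 obj, start=np.array(
                                     [m.m for m in rest]
                                     + [m.b for m in rest
                                        if m.form == "sigmoidal"]),
                                 n_starts=n_starts, ftol=ftol,
                                 seed=int(rng.integers(2**31 - 1)))
            obj_drop = fit.OBJ
        else:
            obj_drop = trace.null_obj
        flagged = (obj_drop - full_obj) < stop_rule.rel_reduction * full_obj
        trace.backward.append((mech.key, obj_drop, flagged))
        if flagged:
            trace.flagged.append(mech.key)
    return trace
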