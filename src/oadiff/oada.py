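"""Order-of-acquisition diffusion analysis (OADA): rate model and likelihood.

OADA is the network-based diffusion analysis variant whose data are only the
order in which naive (individual, option) pairs acquire the behaviour.  At
each acquisition event the probability that a particular pair was the
learner is its acquisition rate divided by the summed rate over the risk set
(all pairs in the same group still naive to their option), a partial
likelihood in the manner of proportional-hazards regression; absolute times
cancel, so only relative rates are identified and the asocial baseline is
fixed at 1.

The relative acquisition rate of pair (i, l) at time t is

    R_il(t) = [ sum_k s_k * x_k(i, l, t) ] * exp(z_i' beta_social)
              + exp(z_i' beta_asocial + gamma * solved_i(t) + delta * 1[l = pull])

where x_k is the cumulative observation count supplied by network component
k (for an option-specific component the count for option l itself; for a
cross-option component the count for the other option; for bias-partitioned
components the count for l restricted to the component's dyads), s_k >= 0 is
the social transmission rate per observation through component k relative to
the asocial baseline, z_i are the standardized individual-level variables
(sex, age, rank), gamma is the boost to asocial learning once the individual
has solved the other option, and delta the asocial effect of the pull option
relative to lift.

Model constraints (which s parameters are free, shared or zero, and which
ILVs enter each side) are described by :class:`OadaModelSpec`; fitting is by
multi-start bounded quasi-Newton on log-s with an explicit comparison
against the s = 0 boundary, and confidence intervals by profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import DataValidationError
from .event_io import OPTIONS, DiffusionDataset
from .obs_networks import DynamicObservationNetwork, NetworkPartition

ASOCIAL_ILV_POOL = ("sex", "age", "rank", "option", "other_option_solved")
SOCIAL_ILV_POOL = ("sex", "age", "rank")
_Z_COLS = ("sex", "age", "rank")

#: chi-square(1) 95% quantile / 2; drop in profiled log-likelihood at the CI edge
PROFILE_DROP_95 = chi2.ppf(0.95, 1) / 2.0

_LOG_S_BOUNDS = (-25.0, 12.0)
_BETA_BOUNDS = (-30.0, 30.0)
_S_BOUNDARY = 1e-4  # fitted s below this triggers the s = 0 comparison


@dataclass(frozen=True)
class NetworkComponent:
    """One network entering the social term, scaled by its own s parameter."""

    name: str
    network: DynamicObservationNetwork
    cross_option: bool = False


def os_co_components(net: DynamicObservationNetwork) -> list[NetworkComponent]:
    """The option-specific / cross-option pair of components on one network."""
    return [NetworkComponent("OS", net), NetworkComponent("CO", net, cross_option=True)]


def partition_components(partition: NetworkPartition) -> list[NetworkComponent]:
    return [NetworkComponent(name, net) for name, net in partition.components.items()]


@dataclass(frozen=True)
class OadaParams:
    """Numeric parameter values of the rate model (reporting scale)."""

    s: Mapping[str, float]
    beta_social: Mapping[str, float] = field(default_factory=dict)
    beta_asocial: Mapping[str, float] = field(default_factory=dict)
    gamma_other_option: float = 0.0
    delta_option: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.s.items():
            if v < 0:
                raise DataValidationError(f"s[{name}] = {v} outside parameter space (s >= 0)")


@dataclass(frozen=True)
class OadaModelSpec:
    """Constraint pattern: s sharing/zeroing plus ILV masks.

    ``s_assignment`` maps each component name to a shared parameter index
    (components with equal index share one s) or ``None`` for s fixed at 0.
    """

    hypothesis: str
    s_assignment: tuple[tuple[str, int | None], ...]
    asocial_ilvs: frozenset[str] = frozenset()
    social_ilvs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.asocial_ilvs) - set(ASOCIAL_ILV_POOL)
        if bad:
            raise ValueError(f"unknown asocial ILVs {sorted(bad)}")
        bad = set(self.social_ilvs) - set(SOCIAL_ILV_POOL)
        if bad:
            raise ValueError(f"unknown social ILVs {sorted(bad)}")
        if all(idx is None for _, idx in self.s_assignment) and self.social_ilvs:
            raise ValueError("an asocial-only model cannot carry social ILVs")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.s_assignment)

    @property
    def s_group_members(self) -> list[tuple[str, ...]]:
        """Component names per free s parameter, in parameter order."""
        groups: dict[int, list[str]] = {}
        for name, idx in self.s_assignment:
            if idx is not None:
                groups.setdefault(idx, []).append(name)
        return [tuple(groups[i]) for i in sorted(groups)]

    def param_labels(self) -> list[str]:
        labels = ["s_" + "+".join(members) for members in self.s_group_members]
        labels += [f"social_{v}" for v in SOCIAL_ILV_POOL if v in self.social_ilvs]
        labels += [f"asocial_{v}" for v in _Z_COLS if v in self.asocial_ilvs]
        if "other_option_solved" in self.asocial_ilvs:
            labels.append("other_option_solved")
        if "option" in self.asocial_ilvs:
            labels.append("option")
        return labels

    @property
    def K(self) -> int:
        return len(self.param_labels())

    def has_variable(self, label: str) -> bool:
        return label in self.param_labels()


# ---------------------------------------------------------------------------
# likelihood data
# ---------------------------------------------------------------------------


@dataclass
class OadaData:
    """Pre-extracted per-event risk-set arrays for fast likelihood evaluation.

    Rows are (individual, option) pairs in the risk set of each acquisition
    event, concatenated over events and groups.  ``expo[k, r]`` is the
    cumulative observation count supplied to row r by component k at the
    event time; ``starts`` delimits event blocks; ``learner_rows`` holds the
    absolute row of each event's learner.
    """

    component_names: tuple[str, ...]
    options: tuple[str, ...]
    expo: np.ndarray  # (C, R)
    z: np.ndarray  # (R, 3) standardized sex/age/rank
    solved: np.ndarray  # (R,)
    is_pull: np.ndarray  # (R,)
    starts: np.ndarray  # (E,)
    learner_rows: np.ndarray  # (E,)
    rows: list[tuple[int, str, str, str]]  # (event number, group, individual, option)

    @property
    def n_events(self) -> int:
        return len(self.starts)

    @property
    def n_rows(self) -> int:
        return len(self.solved)

    def scaled(self, c: float) -> "OadaData":
        """Copy with all network counts multiplied by c (scale-property checks)."""
        return replace(self, expo=self.expo * c)


def prepare_oada_data(
    datasets: Sequence[DiffusionDataset] | DiffusionDataset,
    networks: Mapping[str, Sequence[NetworkComponent]] | Sequence[NetworkComponent],
    options: Sequence[str] = OPTIONS,
) -> OadaData:
    """Assemble the likelihood arrays from per-group datasets and components.

    ``networks`` maps each group to its component list (a bare list is
    accepted for a single dataset).  Component names must agree across
    groups.  Groups contribute independent additive terms: risk sets never
    span groups.
    """
    if isinstance(datasets, DiffusionDataset):
        datasets = [datasets]
    if not isinstance(networks, Mapping):
        if len(datasets) != 1:
            raise ValueError("a component mapping is required with several groups")
        networks = {datasets[0].group: list(networks)}
    options = tuple(options)
    comp_names: tuple[str, ...] | None = None
    expo_cols: list[list[float]] = []
    z_rows: list[np.ndarray] = []
    solved: list[int] = []
    is_pull: list[int] = []
    starts: list[int] = []
    learner_rows: list[int] = []
    rows: list[tuple[int, str, str, str]] = []
    other = {o: (options[1 - i] if len(options) == 2 else None) for i, o in enumerate(options)}

    event_no = 0
    for ds in datasets:
        comps = list(networks[ds.group])
        names = tuple(c.name for c in comps)
        if comp_names is None:
            comp_names = names
        elif names != comp_names:
            raise ValueError(f"component names differ across groups: {names} vs {comp_names}")
        naive = {(i, l) for i in ds.individuals for l in options}
        censor = bool(ds.last_seen)
        for acq in ds.acquisitions:
            if acq.option not in options:
                raise ValueError(f"acquisition option {acq.option!r} not in {options}")
            key = (acq.individual_id, acq.option)
            if key not in naive:
                raise DataValidationError(
                    f"group {ds.group}: learner {key} not naive at event {acq.event_index}"
                )
            t = acq.time_s
            risk = sorted(naive)
            if censor:
                risk = [
                    (i, l)
                    for (i, l) in risk
                    if (i, l) == key or ds.last_seen.get(i, -np.inf) >= t
                ]
            starts.append(len(rows))
            for i, l in risk:
                if (i, l) == key:
                    learner_rows.append(len(rows))
                per_comp = []
                for c in comps:
                    l_eff = other[l] if c.cross_option else l
                    per_comp.append(
                        0.0 if l_eff is None else float(c.network.exposure(i, l_eff, t))
                    )
                expo_cols.append(per_comp)
                z_rows.append(ds.ilv.loc[i, list(_Z_COLS)].to_numpy(dtype=float))
                solved.append(ds.other_option_solved(i, t))
                is_pull.append(int(l == "pull"))
                rows.append((event_no, ds.group, i, l))
            naive.discard(key)
            event_no += 1

    if comp_names is None:
        comp_names = ()
    n_rows = len(rows)
    expo = (
        np.array(expo_cols, dtype=float).T
        if expo_cols and comp_names
        else np.zeros((len(comp_names), n_rows))
    )
    return OadaData(
        component_names=comp_names,
        options=options,
        expo=expo.reshape(len(comp_names), n_rows),
        z=np.array(z_rows, dtype=float).reshape(n_rows, len(_Z_COLS)),
        solved=np.array(solved, dtype=float),
        is_pull=np.array(is_pull, dtype=float),
        starts=np.array(starts, dtype=int),
        learner_rows=np.array(learner_rows, dtype=int),
        rows=rows,
    )


# ---------------------------------------------------------------------------
# rates and likelihood
# ---------------------------------------------------------------------------


def relative_rate(
    exposures: Mapping[str, float],
    params: OadaParams,
    z: Mapping[str, float],
    solved: bool = False,
    is_pull: bool = False,
) -> float:
    """R_il for a single pair given its exposure counts and covariates."""
    zs = sum(params.beta_social.get(v, 0.0) * z.get(v, 0.0) for v in SOCIAL_ILV_POOL)
    za = sum(params.beta_asocial.get(v, 0.0) * z.get(v, 0.0) for v in _Z_COLS)
    social = sum(params.s.get(k, 0.0) * x for k, x in exposures.items()) * np.exp(zs)
    asocial = np.exp(
        za
        + params.gamma_other_option * float(solved)
        + params.delta_option * float(is_pull)
    )
    return float(social + asocial)


def rate(
    individual_id: str,
    option: str,
    t: float,
    params: OadaParams,
    components: Sequence[NetworkComponent],
    dataset: DiffusionDataset,
) -> float:
    """Relative acquisition rate of one naive (individual, option) pair at t."""
    other = {OPTIONS[0]: OPTIONS[1], OPTIONS[1]: OPTIONS[0]}
    exposures = {
        c.name: c.network.exposure(individual_id, other[option] if c.cross_option else option, t)
        for c in components
    }
    z = dataset.ilv.loc[individual_id, list(_Z_COLS)].to_dict()
    return relative_rate(
        exposures,
        params,
        z,
        solved=bool(dataset.other_option_solved(individual_id, t)),
        is_pull=option == "pull",
    )


def _param_arrays(params: OadaParams, data: OadaData):
    s_vec = np.array([params.s.get(name, 0.0) for name in data.component_names])
    bs = np.array([params.beta_social.get(v, 0.0) for v in _Z_COLS])
    ba = np.array([params.beta_asocial.get(v, 0.0) for v in _Z_COLS])
    return s_vec, bs, ba


def _row_rates(data: OadaData, s_vec, bs, ba, gamma, delta):
    social_lin = data.z @ bs
    social = (s_vec @ data.expo) * np.exp(social_lin) if len(s_vec) else np.zeros(data.n_rows)
    asocial = np.exp(data.z @ ba + gamma * data.solved + delta * data.is_pull)
    return social, asocial


def log_likelihood(params: OadaParams, data: OadaData) -> float:
    """OADA partial log-likelihood: sum over events of log(R_learner / sum R)."""
    if data.n_events == 0:
        return 0.0
    s_vec, bs, ba = _param_arrays(params, data)
    social, asocial = _row_rates(
        data, s_vec, bs, ba, params.gamma_other_option, params.delta_option
    )
    R = social + asocial
    denom = np.add.reduceat(R, data.starts)
    if np.any(denom <= 0):
        raise DataValidationError("event with empty or zero-rate risk set")
    return float(np.sum(np.log(R[data.learner_rows])) - np.sum(np.log(denom)))


def event_probabilities(params: OadaParams, data: OadaData) -> list[np.ndarray]:
    """Per event, the risk-set probability vector (sums to 1)."""
    s_vec, bs, ba = _param_arrays(params, data)
    social, asocial = _row_rates(
        data, s_vec, bs, ba, params.gamma_other_option, params.delta_option
    )
    R = social + asocial
    bounds = list(data.starts) + [data.n_rows]
    return [
        R[bounds[e] : bounds[e + 1]] / R[bounds[e] : bounds[e + 1]].sum()
        for e in range(data.n_events)
    ]


# ---------------------------------------------------------------------------
# packed parameterization and fitting
# ---------------------------------------------------------------------------


def _expand(spec: OadaModelSpec, x: np.ndarray, data: OadaData):
    """Packed optimizer vector -> (s per component, bs, ba, gamma, delta)."""
    n_s = len(spec.s_group_members)
    idx_of = dict(spec.s_assignment)
    s_vec = np.array(
        [0.0 if idx_of[name] is None else np.exp(x[_s_pos(spec, idx_of[name])])
         for name in data.component_names]
    )
    pos = n_s
    bs = np.zeros(len(_Z_COLS))
    for j, v in enumerate(SOCIAL_ILV_POOL):
        if v in spec.social_ilvs:
            bs[j] = x[pos]
            pos += 1
    ba = np.zeros(len(_Z_COLS))
    for j, v in enumerate(_Z_COLS):
        if v in spec.asocial_ilvs:
            ba[j] = x[pos]
            pos += 1
    gamma = 0.0
    if "other_option_solved" in spec.asocial_ilvs:
        gamma = x[pos]
        pos += 1
    delta = 0.0
    if "option" in spec.asocial_ilvs:
        delta = x[pos]
        pos += 1
    return s_vec, bs, ba, gamma, delta


def _s_pos(spec: OadaModelSpec, group_idx: int) -> int:
    ordered = sorted({i for _, i in spec.s_assignment if i is not None})
    return ordered.index(group_idx)


def _nll_and_grad(x: np.ndarray, spec: OadaModelSpec, data: OadaData):
    s_vec, bs, ba, gamma, delta = _expand(spec, x, data)
    social_lin = data.z @ bs
    exp_social = np.exp(social_lin)
    per_comp = data.expo * s_vec[:, None] if len(s_vec) else np.zeros((0, data.n_rows))
    social = per_comp.sum(axis=0) * exp_social
    asocial = np.exp(data.z @ ba + gamma * data.solved + delta * data.is_pull)
    R = social + asocial
    denom = np.add.reduceat(R, data.starts)
    ll = np.sum(np.log(R[data.learner_rows])) - np.sum(np.log(denom))

    # dR/dtheta rows for every free parameter, in packed order
    grads = []
    idx_of = dict(spec.s_assignment)
    for members in spec.s_group_members:
        mask = np.array([name in members for name in data.component_names])
        grads.append(per_comp[mask].sum(axis=0) * exp_social)  # d/d log s
    for j, v in enumerate(SOCIAL_ILV_POOL):
        if v in spec.social_ilvs:
            grads.append(social * data.z[:, j])
    for j, v in enumerate(_Z_COLS):
        if v in spec.asocial_ilvs:
            grads.append(asocial * data.z[:, j])
    if "other_option_solved" in spec.asocial_ilvs:
        grads.append(asocial * data.solved)
    if "option" in spec.asocial_ilvs:
        grads.append(asocial * data.is_pull)

    g = np.empty(len(grads))
    for p, dR in enumerate(grads):
        g[p] = np.sum(dR[data.learner_rows] / R[data.learner_rows]) - np.sum(
            np.add.reduceat(dR, data.starts) / denom
        )
    return -ll, -g


@dataclass
class FitConfig:
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 500


@dataclass
class OadaFit:
    """Maximum-likelihood fit of one constrained OADA model."""

    spec: OadaModelSpec
    params: OadaParams
    estimates: dict[str, float]  # label -> natural-scale MLE
    log_likelihood: float
    K: int
    aicc: float
    n_events: int
    converged: bool
    flags: tuple[str, ...] = ()


def _bounds(spec: OadaModelSpec) -> list[tuple[float, float]]:
    n_s = len(spec.s_group_members)
    return [_LOG_S_BOUNDS] * n_s + [_BETA_BOUNDS] * (spec.K - n_s)


def _zero_s_group(spec: OadaModelSpec, group_pos: int) -> OadaModelSpec:
    """Spec with the ``group_pos``-th free s group constrained to zero."""
    ordered = sorted({i for _, i in spec.s_assignment if i is not None})
    drop = ordered[group_pos]
    assignment = tuple(
        (name, None if idx == drop else idx) for name, idx in spec.s_assignment
    )
    social = (
        frozenset()
        if all(idx is None for _, idx in assignment)
        else spec.social_ilvs
    )
    return replace(spec, s_assignment=assignment, social_ilvs=social)


def _params_from_packed(spec: OadaModelSpec, x: np.ndarray, data: OadaData) -> OadaParams:
    s_vec, bs, ba, gamma, delta = _expand(spec, x, data)
    return OadaParams(
        s={name: float(v) for name, v in zip(data.component_names, s_vec)},
        beta_social={
            v: float(bs[j]) for j, v in enumerate(_Z_COLS) if v in spec.social_ilvs
        },
        beta_asocial={
            v: float(ba[j]) for j, v in enumerate(_Z_COLS) if v in spec.asocial_ilvs
        },
        gamma_other_option=float(gamma),
        delta_option=float(delta),
    )


def _optimize(spec: OadaModelSpec, data: OadaData, config: FitConfig,
              x0_extra: Sequence[np.ndarray] = ()):
    n_free = spec.K
    if n_free == 0:
        x = np.empty(0)
        nll, _ = _nll_and_grad(x, spec, data)
        return x, -nll, True
    rng = np.random.default_rng(config.seed)
    n_s = len(spec.s_group_members)
    base = np.concatenate([np.full(n_s, np.log(0.1)), np.zeros(n_free - n_s)])
    starts = [base] + list(x0_extra)
    while len(starts) < max(1, config.n_starts):
        starts.append(base + rng.normal(scale=1.5, size=n_free))
    best = None
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(x0, [b[0] for b in _bounds(spec)], [b[1] for b in _bounds(spec)]),
            args=(spec, data),
            jac=True,
            method="L-BFGS-B",
            bounds=_bounds(spec),
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    grad_ok = np.all(np.abs(best.jac) < 1e-2) or _at_bounds(best.x, spec)
    return best.x, -float(best.fun), bool(best.success and grad_ok)


def _at_bounds(x: np.ndarray, spec: OadaModelSpec) -> bool:
    n_s = len(spec.s_group_members)
    return bool(np.any(x[:n_s] <= _LOG_S_BOUNDS[0] + 1e-6))


def fit(
    spec: OadaModelSpec,
    data: OadaData,
    config: FitConfig | None = None,
) -> OadaFit:
    """Fit one constrained model by multi-start bounded quasi-Newton.

    s parameters are optimized on the log scale; any s estimated near zero
    is compared against the exact s = 0 constrained optimum, and the better
    of the two is reported (the estimate then being exactly 0 while K keeps
    counting the parameter as free).  A model whose free s multiplies an
    all-zero network is flagged ``unidentifiable``.
    """
    from .model_selection import aicc  # local import: model_selection imports this module

    config = config or FitConfig()
    if set(spec.component_names) != set(data.component_names):
        raise ValueError(
            f"spec components {spec.component_names} do not match data {data.component_names}"
        )
    flags: list[str] = []
    x, ll, converged = _optimize(spec, data, config)
    params = _params_from_packed(spec, x, data)

    # boundary comparison at s = 0 for each nearly-vanishing s group
    n_s = len(spec.s_group_members)
    for pos in range(n_s - 1, -1, -1):
        if np.exp(x[pos]) >= _S_BOUNDARY:
            continue
        sub = _zero_s_group(spec, pos)
        keep = [p for p in range(spec.K) if p != pos]
        keep = [p for p in keep if spec.param_labels()[p] in sub.param_labels()]
        x0 = x[keep] if len(keep) == sub.K else None
        sub_x, sub_ll, sub_conv = _optimize(
            sub, data, replace(config, n_starts=1), [x0] if x0 is not None else ()
        )
        if sub_ll >= ll - 1e-8:
            sub_params = _params_from_packed(sub, sub_x, data)
            zeroed = set(spec.s_group_members[pos])
            params = OadaParams(
                s={k: (0.0 if k in zeroed else sub_params.s[k]) for k in params.s},
                beta_social={
                    v: sub_params.beta_social.get(v, 0.0) for v in spec.social_ilvs
                },
                beta_asocial=sub_params.beta_asocial,
                gamma_other_option=sub_params.gamma_other_option,
                delta_option=sub_params.delta_option,
            )
            ll = sub_ll
            converged = converged or sub_conv
            flags.append(f"s boundary: {'+'.join(spec.s_group_members[pos])} = 0")

    # a free s multiplying an all-zero network is unidentifiable: report 0
    for members in spec.s_group_members:
        total = sum(
            data.expo[data.component_names.index(m)].sum()
            for m in members
            if m in data.component_names
        )
        if total == 0:
            flags.append(f"unidentifiable: zero network for {'+'.join(members)}")
            params = replace(
                params, s={k: (0.0 if k in members else v) for k, v in params.s.items()}
            )

    estimates = dict(zip(spec.param_labels(), _natural_estimates(spec, params)))
    n = data.n_events
    return OadaFit(
        spec=spec,
        params=params,
        estimates=estimates,
        log_likelihood=ll,
        K=spec.K,
        aicc=aicc(ll, spec.K, n) if n > spec.K + 1 else np.inf,
        n_events=n,
        converged=converged,
        flags=tuple(flags),
    )


def _natural_estimates(spec: OadaModelSpec, params: OadaParams) -> list[float]:
    vals = [params.s[members[0]] for members in spec.s_group_members]
    vals += [params.beta_social[v] for v in SOCIAL_ILV_POOL if v in spec.social_ilvs]
    vals += [params.beta_asocial[v] for v in _Z_COLS if v in spec.asocial_ilvs]
    if "other_option_solved" in spec.asocial_ilvs:
        vals.append(params.gamma_other_option)
    if "option" in spec.asocial_ilvs:
        vals.append(params.delta_option)
    return vals


# ---------------------------------------------------------------------------
# profile likelihood intervals
# ---------------------------------------------------------------------------


def profile_interval(
    prof: Callable[[float], float],
    mle: float,
    max_ll: float,
    drop: float = PROFILE_DROP_95,
    lower_bound: float | None = None,
    tol: float = 1e-4,
    max_expand: int = 60,
) -> tuple[float, float]:
    """Generic 1-D profile-likelihood interval by bracketing + bisection.

    ``prof(v)`` is the profiled log-likelihood at parameter value v.  An
    endpoint where the profile never drops below ``max_ll - drop`` is open:
    ``lower_bound`` (or -inf) on the left, +inf on the right.
    """
    target = max_ll - drop

    def bisect(lo: float, hi: float, lo_below: bool) -> float:
        # invariant: profile crosses target between lo and hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            below = prof(mid) < target
            if below == lo_below:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # lower endpoint
    step = max(abs(mle), 0.5)
    a, lower = mle, None
    for _ in range(max_expand):
        b = a - step if lower_bound is None else max(lower_bound, a - step)
        if prof(b) < target:
            lower = bisect(b, a, lo_below=True)
            break
        a = b
        step *= 2.0
        if lower_bound is not None and a <= lower_bound:
            lower = lower_bound
            break
    if lower is None:
        lower = -np.inf if lower_bound is None else lower_bound

    step = max(abs(mle), 0.5)
    a, upper = mle, None
    for _ in range(max_expand):
        b = a + step
        if prof(b) < target:
            lo_, hi_ = a, b
            while hi_ - lo_ > tol:
                mid = 0.5 * (lo_ + hi_)
                if prof(mid) < target:
                    hi_ = mid
                else:
                    lo_ = mid
            upper = 0.5 * (lo_ + hi_)
            break
        a = b
        step *= 2.0
    if upper is None:
        upper = np.inf
    return float(lower), float(upper)


def profile_ci(
    fit_result: OadaFit,
    param_label: str,
    data: OadaData,
    level: float = 0.95,
    tol: float = 1e-4,
    config: FitConfig | None = None,
) -> tuple[float, float]:
    """Profile-likelihood CI for one free parameter of a fitted model.

    All other parameters are re-optimized at each grid value; s parameters
    are truncated at 0 (the exact constrained fit is used at the boundary).
    A flat profile yields an open endpoint (0 or +inf for s).
    """
    spec = fit_result.spec
    labels = spec.param_labels()
    if param_label not in labels:
        raise ValueError(f"{param_label!r} is not a free parameter of this model")
    pos = labels.index(param_label)
    is_s = pos < len(spec.s_group_members)
    config = config or FitConfig(n_starts=1)
    drop = chi2.ppf(level, 1) / 2.0
    mle = fit_result.estimates[param_label]
    warm = _pack_estimates(spec, fit_result.estimates)

    def prof(v: float) -> float:
        if is_s and v <= 0:
            sub = _zero_s_group(spec, pos)
            keep = [p for p, lab in enumerate(labels) if lab in sub.param_labels()]
            _, ll, _ = _optimize(sub, data, config, [warm[keep]] if len(keep) == sub.K else ())
            return ll
        fixed_spec = _FixedParam(spec, pos, np.log(v) if is_s else v)
        x0 = np.delete(warm, pos)
        _, ll, _ = _optimize_fixed(fixed_spec, data, config, x0)
        return ll

    return profile_interval(
        prof,
        mle,
        fit_result.log_likelihood,
        drop=drop,
        lower_bound=0.0 if is_s else None,
        tol=tol,
    )


def _pack_estimates(spec: OadaModelSpec, estimates: Mapping[str, float]) -> np.ndarray:
    x = []
    for p, label in enumerate(spec.param_labels()):
        v = estimates[label]
        if p < len(spec.s_group_members):
            x.append(np.log(max(v, 1e-10)))
        else:
            x.append(v)
    return np.array(x)


@dataclass(frozen=True)
class _FixedParam:
    spec: OadaModelSpec
    pos: int
    value: float  # on the packed (optimizer) scale


def _optimize_fixed(fx: _FixedParam, data: OadaData, config: FitConfig, x0: np.ndarray):
    spec, pos, val = fx.spec, fx.pos, fx.value
    n_free = spec.K - 1
    if n_free == 0:
        full = np.array([val])
        nll, _ = _nll_and_grad(full, spec, data)
        return np.empty(0), -nll, True

    def fun(xr: np.ndarray):
        full = np.insert(xr, pos, val)
        nll, g = _nll_and_grad(full, spec, data)
        return nll, np.delete(g, pos)

    bounds = [b for p, b in enumerate(_bounds(spec)) if p != pos]
    best = None
    rng = np.random.default_rng(config.seed)
    starts = [x0] + [x0 + rng.normal(scale=1.0, size=n_free) for _ in range(config.n_starts - 1)]
    for s0 in starts:
        res = minimize(
            fun,
            np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds]),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -float(best.fun), bool(best.success)


# ---------------------------------------------------------------------------
# pathway attribution
# ---------------------------------------------------------------------------


def percent_by_pathway(fit_result: OadaFit, data: OadaData) -> dict[str, float]:
    """Estimated % of acquisition events attributable to each pathway.

    For each event, the learner's probability mass on component k is
    s_k * x_k * exp(social ILV term) / R_learner; percentages are 100 times
    the mean over events, the remainder being asocial.
    """
    params = fit_result.params
    s_vec, bs, ba = _param_arrays(params, data)
    social_lin = data.z @ bs
    asocial = np.exp(
        data.z @ ba
        + params.gamma_other_option * data.solved
        + params.delta_option * data.is_pull
    )
    per_comp = data.expo * s_vec[:, None] if len(s_vec) else np.zeros((0, data.n_rows))
    R = per_comp.sum(axis=0) * np.exp(social_lin) + asocial
    lr = data.learner_rows
    out: dict[str, float] = {}
    total = 0.0
    for k, name in enumerate(data.component_names):
        pk = per_comp[k, lr] * np.exp(social_lin[lr]) / R[lr]
        pct = float(100.0 * pk.mean()) if data.n_events else 0.0
        out[name] = pct
        total += pct
    out["asocial"] = 100.0 - total if data.n_events else 100.0
    return out
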