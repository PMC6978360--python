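"""Model enumeration, AICc multi-model inference and model averaging.

The analysis compares constraint hypotheses on the social-transmission
parameters -- for the option-specific/cross-option analysis: (a) a free rate
per pathway, (b) equal rates, (c) option-specific transmission only, (d)
cross-option only, and (e) asocial learning -- crossed with every subset of
five asocial individual-level effects (sex, age, rank, option, other option
solved) and three social ones (sex, age, rank).  That yields 256 models per
hypothesis a-d and 32 for the asocial hypothesis, 1056 in total.  Bias
analyses (rank, sex, age, kin) use the partitioned networks instead, with
hypotheses free / equal / only-one-pathway / asocial.

Support for a hypothesis is the summed Akaike weight of its models.  The
asocial set contains far fewer models, so by default its total weight is
computed but flagged: support for asocial learning should be judged from
the confidence intervals on s instead.  Model-averaged estimates use
full-model averaging (a variable absent from a model contributes 0) on the
estimation scale, back-transformed with exp() for ILV effects; the CI
attached to an averaged estimate is the profile CI from the best model
containing that variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .oada import (
    ASOCIAL_ILV_POOL,
    SOCIAL_ILV_POOL,
    FitConfig,
    OadaData,
    OadaFit,
    OadaModelSpec,
    fit,
    profile_ci,
)

ANALYSES = ("os_co", "rank_bias", "sex_bias", "age_bias", "kin_bias")

_ANALYSIS_COMPONENTS = {
    "os_co": ("OS", "CO"),
    "rank_bias": ("HL", "LH"),
    "sex_bias": ("from_female", "from_male"),
    "age_bias": (
        "adult_to_adult",
        "adult_to_juvenile",
        "juvenile_to_adult",
        "juvenile_to_juvenile",
    ),
    "kin_bias": ("mother_to_offspring", "offspring_to_mother", "siblings", "nonkin"),
}


def analysis_components(analysis: str) -> tuple[str, ...]:
    try:
        return _ANALYSIS_COMPONENTS[analysis]
    except KeyError:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}") from None


def _subsets(pool: Sequence[str]):
    for r in range(len(pool) + 1):
        yield from (frozenset(c) for c in combinations(pool, r))


def _hypotheses(analysis: str) -> list[tuple[str, tuple[int | None, ...]]]:
    comps = analysis_components(analysis)
    n = len(comps)
    out: list[tuple[str, tuple[int | None, ...]]] = []
    if analysis == "os_co":
        out.append(("a_free", (0, 1)))
        out.append(("b_equal", (0, 0)))
        out.append(("c_os_only", (0, None)))
        out.append(("d_co_only", (None, 0)))
    else:
        out.append(("a_free", tuple(range(n))))
        out.append(("b_equal", tuple(0 for _ in comps)))
        for k, name in enumerate(comps):
            out.append((f"only_{name}", tuple(0 if i == k else None for i in range(n))))
    out.append(("e_asocial", tuple(None for _ in comps)))
    return out


def enumerate_models(analysis: str) -> list[OadaModelSpec]:
    """All constraint-by-ILV model specifications for one analysis.

    Social hypotheses are crossed with every asocial and social ILV subset;
    the asocial hypothesis only with asocial subsets.
    """
    comps = analysis_components(analysis)
    specs: list[OadaModelSpec] = []
    for hyp, assignment in _hypotheses(analysis):
        s_assignment = tuple(zip(comps, assignment))
        social_masks = (
            [frozenset()] if hyp == "e_asocial" else list(_subsets(SOCIAL_ILV_POOL))
        )
        for a_mask in _subsets(ASOCIAL_ILV_POOL):
            for s_mask in social_masks:
                specs.append(
                    OadaModelSpec(
                        hypothesis=hyp,
                        s_assignment=s_assignment,
                        asocial_ilvs=a_mask,
                        social_ilvs=s_mask,
                    )
                )
    return specs


def aicc(logL: float, K: int, n: int) -> float:
    """Akaike's information criterion with the small-sample correction."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """exp(-dAICc/2), normalized over the model set."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("empty model set")
    rel = np.exp(-(a - np.nanmin(a)) / 2.0)
    rel = np.where(np.isfinite(a), rel, 0.0)
    return rel / rel.sum()


@dataclass
class ModelSetResult:
    """Fits, weights and bookkeeping for one fitted model set."""

    analysis: str
    fits: list[OadaFit]
    weights: np.ndarray  # over all fits; non-converged carry weight 0
    excluded: list[int] = field(default_factory=list)  # indices of non-converged fits

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.weights))

    def best_fit_with(self, label: str) -> OadaFit | None:
        cands = [
            (f.aicc, i)
            for i, f in enumerate(self.fits)
            if f.spec.has_variable(label) and i not in self.excluded
        ]
        return self.fits[min(cands)[1]] if cands else None


def fit_model_set(
    specs: Sequence[OadaModelSpec],
    data: OadaData,
    config: FitConfig | None = None,
    analysis: str = "",
) -> ModelSetResult:
    """Fit every spec and weight the converged fits by AICc.

    Non-converged fits are excluded from weighting and listed in
    ``excluded`` (their reasons are in each fit's flags).
    """
    fits = [fit(spec, data, config) for spec in specs]
    excluded = [i for i, f in enumerate(fits) if not f.converged]
    aiccs = np.array(
        [f.aicc if i not in excluded else np.inf for i, f in enumerate(fits)]
    )
    return ModelSetResult(analysis=analysis, fits=fits, weights=akaike_weights(aiccs),
                          excluded=excluded)


def hypothesis_support(result: ModelSetResult, weights_exclude_asocial: bool = False) -> dict[str, float]:
    """Total Akaike weight (%) per constraint hypothesis.

    With ``weights_exclude_asocial`` the weights are renormalized over the
    social hypotheses only; the asocial set's support should in any case be
    judged by the s confidence intervals, not by its weight, because it
    contains far fewer models.
    """
    w = result.weights.copy()
    if weights_exclude_asocial:
        keep = np.array([f.spec.hypothesis != "e_asocial" for f in result.fits])
        w = np.where(keep, w, 0.0)
        if w.sum() > 0:
            w = w / w.sum()
    out: dict[str, float] = {}
    for f, wi in zip(result.fits, w):
        out[f.spec.hypothesis] = out.get(f.spec.hypothesis, 0.0) + 100.0 * float(wi)
    return out


def variable_support(result: ModelSetResult) -> dict[str, float]:
    """Per free-parameter label, summed weight (%) of models containing it."""
    out: dict[str, float] = {}
    for f, wi in zip(result.fits, result.weights):
        for label in f.spec.param_labels():
            out[label] = out.get(label, 0.0) + 100.0 * float(wi)
    return out


@dataclass(frozen=True)
class AveragedEstimate:
    label: str
    estimate: float  # estimation scale (linear predictor; s natural)
    multiplicative: float | None  # exp(estimate) for ILV effects, None for s
    support_pct: float
    ci: tuple[float, float] | None
    ci_source_hypothesis: str | None


def model_average(
    result: ModelSetResult,
    label: str,
    data: OadaData | None = None,
    compute_ci: bool = False,
    ci_config: FitConfig | None = None,
) -> AveragedEstimate:
    """Full-model-averaged estimate of one parameter.

    The coefficient is taken as 0 in models excluding the variable; the
    weighted mean is formed on the estimation scale and, for ILV effects,
    back-transformed with exp() to the multiplicative scale.  s parameters
    average on their natural scale.  The CI (optional, needs ``data``) is
    the profile interval from the best-AICc model containing the variable.
    """
    present = [f.spec.has_variable(label) for f in result.fits]
    if not any(present):
        raise ValueError(f"variable {label!r} appears in no model of the set")
    est = 0.0
    support = 0.0
    for f, wi, has in zip(result.fits, result.weights, present):
        if has:
            est += float(wi) * f.estimates[label]
            support += 100.0 * float(wi)
    is_s = label.startswith("s_")
    ci = None
    src = None
    if compute_ci:
        if data is None:
            raise ValueError("data is required to compute a profile CI")
        best = result.best_fit_with(label)
        if best is not None:
            ci = profile_ci(best, label, data, config=ci_config)
            src = best.spec.hypothesis
    return AveragedEstimate(
        label=label,
        estimate=est,
        multiplicative=None if is_s else float(np.exp(est)),
        support_pct=support,
        ci=ci,
        ci_source_hypothesis=src,
    )
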