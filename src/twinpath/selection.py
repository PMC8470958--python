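"""Parsimony model selection and decomposition reports.

Selection follows standard twin-modelling practice: submodels are compared
to their reference model by the likelihood-ratio test (difference in
-2 log-likelihood against a chi-square with the difference in free
parameters), and the most parsimonious model without significant fit
deterioration is retained (alpha = 0.05 by default).

A deliberate, documented approximation: variance components are tested at
the boundary of their parameter space (a variance cannot be negative), so
the naive chi-square reference distribution is conservative for removal —
the true null is a chi-bar-square mixture with more mass near zero.  We use
the naive chi-square throughout, as is common in twin modelling.  Tests of
non-boundary parameters (e.g. covariate slopes) are exactly calibrated.

The ACE-vs-ADE choice uses the classical twin-correlation screen: under
ACE, r_MZ = a^2 + c^2 <= 2 r_DZ = a^2 + 2 c^2, so r_MZ > 2 r_DZ signals
non-additive genetic variance and the ADE family is used instead.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import TwinCorrelations, TwinDataset, complete_case_filter, twin_correlations
from .model import (
    ContractError,
    FittedModel,
    ModelSpec,
    PathParameters,
    VarianceDecomposition,
    fit_model,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LRTResult",
    "SelectionStep",
    "SelectionTrace",
    "DecompositionReport",
    "lrt",
    "choose_model_family",
    "univariate_model_sequence",
    "ip_backward_elimination",
    "render_report",
]


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of a nested submodel against a fuller one."""

    delta_minus2ll: float
    delta_df: int
    p_value: float


def lrt(full: FittedModel, sub: FittedModel, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of ``sub`` (nested) against ``full``.

    The statistic is clamped at zero (an optimizer can land a submodel a
    hair below its parent).  With zero degrees of freedom the models are
    equivalent and p = 1 whenever the statistic is within tolerance.
    """
    if not sub.spec.is_nested_in(full.spec):
        raise ContractError("submodel spec is not nested in the full model's spec")
    delta_df = full.n_free_params - sub.n_free_params
    if delta_df < 0:
        raise ContractError("submodel has more free parameters than the full model")
    delta = max(0.0, sub.minus2ll - full.minus2ll)
    if delta_df == 0:
        p = 1.0 if delta <= tol else 0.0
    else:
        p = float(sps.chi2.sf(delta, delta_df))
    return LRTResult(delta_minus2ll=delta, delta_df=delta_df, p_value=p)


def choose_model_family(corr: TwinCorrelations) -> str:
    """ACE-vs-ADE screen from the pattern of twin correlations: ADE when
    r_MZ > 2 r_DZ, otherwise ACE (ties go to ACE)."""
    return "ADE" if corr.r_mz > 2.0 * corr.r_dz else "ACE"


@dataclass
class SelectionStep:
    """One candidate considered during selection."""

    label: str
    spec: ModelSpec
    fitted: FittedModel
    lrt: LRTResult  # against the reference model of the step (see operation)
    kept: bool = False
    lrt_vs_full: LRTResult | None = None


@dataclass
class SelectionTrace:
    """Ordered record of every candidate fitted, plus the selection."""

    full: FittedModel
    steps: list[SelectionStep]
    selected: FittedModel
    selected_label: str = "full"


# ---------------------------------------------------------------------------
# Univariate submodel sequence


_UNIVARIATE_SUBMODELS = {
    "ACE": [("AE", ("A", "E")), ("CE", ("C", "E")), ("E", ("E",))],
    "ADE": [("AE", ("A", "E")), ("E", ("E",))],
}


def univariate_model_sequence(
    dataset: TwinDataset,
    trait: str,
    alpha: float = 0.05,
    *,
    seed: int = 0,
    n_starts: int = 10,
    adjust_age: bool = True,
    adjust_sex: bool = True,
) -> SelectionTrace:
    """Fit the full three-source univariate model (ACE or ADE per the
    correlation screen) and its nested submodels, each LRT-compared with
    the full model; select the submodel with the fewest free parameters
    among those with p >= alpha (ties broken by lower AIC), defaulting to
    the full model when every drop is significant."""
    data = complete_case_filter(dataset, [trait])
    corr = twin_correlations(data, trait)
    family = choose_model_family(corr)
    full_sources = ("A", "C", "E") if family == "ACE" else ("A", "D", "E")
    full_spec = ModelSpec.univariate(
        trait, sources=full_sources, adjust_age=adjust_age, adjust_sex=adjust_sex
    )
    full = fit_model(data, full_spec, n_starts=n_starts, seed=seed)
    steps: list[SelectionStep] = []
    for label, sources in _UNIVARIATE_SUBMODELS[family]:
        spec = ModelSpec.univariate(
            trait, sources=sources, adjust_age=adjust_age, adjust_sex=adjust_sex
        )
        fitted = fit_model(data, spec, n_starts=n_starts, seed=seed)
        res = lrt(full, fitted)
        steps.append(SelectionStep(label, spec, fitted, res, lrt_vs_full=res))
    admissible = [s for s in steps if s.lrt.p_value >= alpha and s.fitted.converged]
    if admissible:
        best = min(
            admissible, key=lambda s: (s.fitted.n_free_params, s.fitted.aic)
        )
        best.kept = True
        selected, label = best.fitted, best.label
    else:
        selected, label = full, family
    return SelectionTrace(full=full, steps=steps, selected=selected, selected_label=label)


# ---------------------------------------------------------------------------
# Independent-pathway backward elimination


def _removable_elements(spec: ModelSpec):
    for S in spec.sources:
        if spec.common_free[S]:
            yield ("common", S, None)
        for i, free in enumerate(spec.specific_free[S]):
            if free:
                yield ("specific", S, i)


def _drop(spec: ModelSpec, element) -> ModelSpec:
    kind, S, i = element
    return spec.drop_common(S) if kind == "common" else spec.drop_specific(S, i)


def _element_label(spec: ModelSpec, element) -> str:
    kind, S, i = element
    if kind == "common":
        return f"drop common {S}"
    return f"drop specific {S}:{spec.traits[i]}"


def _leaves_trait_varianceless(spec: ModelSpec) -> bool:
    p = spec.n_traits
    free = np.zeros(p)
    for S in spec.sources:
        if spec.common_free[S]:
            free += 1.0
        free += np.array(spec.specific_free[S], float)
    return bool(np.any(free == 0))


def _zeroed_init(params: PathParameters, element) -> PathParameters:
    out = params.copy()
    kind, S, i = element
    if kind == "common":
        out.loadings[S] = np.zeros_like(out.loadings[S])
    else:
        out.specifics[S][i] = 0.0
    return out


def ip_backward_elimination(
    dataset: TwinDataset,
    traits,
    alpha: float = 0.05,
    *,
    seed: int = 0,
    n_starts: int = 10,
    candidate_starts: int = 3,
    sources: tuple[str, ...] = ("A", "C", "E"),
    adjust_age: bool = True,
    adjust_sex: bool = True,
) -> SelectionTrace:
    """Backward elimination over an independent-pathway model.

    Starting from the full model (common A, C, E factors plus A, C, E
    specific paths for every trait), each currently-free element — a common
    factor as a whole, or one specific path — is tentatively fixed to zero
    and LRT-compared with the *current* model; the element with the largest
    p-value among those with p >= alpha is removed, and the search repeats.
    Candidates that would leave some trait with no free path (zero total
    variance) are skipped.  The final model is additionally gated by an LRT
    against the initial full model: if that test is significant, the last
    accepted model that still passes it is returned instead.
    """
    traits = tuple(traits)
    if len(traits) < 3:
        raise ContractError("independent-pathway selection needs >=3 traits")
    data = complete_case_filter(dataset, traits)
    full_spec = ModelSpec.independent_pathway(
        traits, sources=sources, adjust_age=adjust_age, adjust_sex=adjust_sex
    )
    full = fit_model(data, full_spec, n_starts=n_starts, seed=seed)
    steps: list[SelectionStep] = []
    current = full
    accepted: list[tuple[str, FittedModel, LRTResult]] = [
        ("full", full, lrt(full, full))
    ]
    iteration = 0
    while True:
        iteration += 1
        candidates = []
        for idx, element in enumerate(_removable_elements(current.spec)):
            cand_spec = _drop(current.spec, element)
            if _leaves_trait_varianceless(cand_spec):
                logger.info(
                    "skipping %s: it would zero a trait's total variance",
                    _element_label(current.spec, element),
                )
                continue
            cand_seed = (seed * 7919 + iteration * 101 + idx) % (2**31)
            fitted = fit_model(
                data,
                cand_spec,
                n_starts=candidate_starts,
                seed=cand_seed,
                init=_zeroed_init(current.params, element),
            )
            res = lrt(current, fitted)
            step = SelectionStep(
                _element_label(current.spec, element),
                cand_spec,
                fitted,
                res,
                lrt_vs_full=lrt(full, fitted),
            )
            steps.append(step)
            if fitted.converged:
                candidates.append(step)
        droppable = [s for s in candidates if s.lrt.p_value >= alpha]
        if not droppable:
            break
        # A common factor loading on a single trait is observationally
        # equivalent to that trait's specific path, so at (near-)tied
        # p-values the search could strand an empty common factor by
        # removing the specific instead.  Resolve the indeterminacy toward
        # parsimony: whole common factors (p parameters) are removed before
        # individual specific paths whenever both are droppable.
        common_droppable = [s for s in droppable if s.label.startswith("drop common")]
        pool = common_droppable or droppable
        chosen = max(pool, key=lambda s: s.lrt.p_value)
        chosen.kept = True
        current = chosen.fitted
        accepted.append((chosen.label, current, chosen.lrt_vs_full))
    # final gate against the initial full model
    selected_label, selected = "full", full
    for label, model, vs_full in reversed(accepted):
        if vs_full.p_value >= alpha:
            selected_label, selected = label, model
            break
    if selected is not current:
        logger.info(
            "final model failed the gate vs the full model; backtracked to %s",
            selected_label,
        )
    return SelectionTrace(
        full=full, steps=steps, selected=selected, selected_label=selected_label
    )


# ---------------------------------------------------------------------------
# Reports


def _percent(x: float) -> int:
    """Round a share to integer percent, half away from zero (half-up for
    the nonnegative shares used here)."""
    return int(math.floor(x * 100.0 + 0.5))


@dataclass
class DecompositionReport:
    """Rendered decomposition: integer-percent three-block table plus the
    fit-statistics table of every candidate considered."""

    model_name: str
    decomposition: VarianceDecomposition
    fit_table: pd.DataFrame
    selected_label: str

    _SOURCE_WORD = {"A": "Genetic", "C": "Shared environmental", "D": "Dominance", "E": "Environmental"}

    def shares_frame(self) -> pd.DataFrame:
        """Pre-rounding floating-point shares, one row per component, one
        column per trait.  Serializes to CSV and back losslessly."""
        d = self.decomposition
        rows, index = [], []
        for block, store in (("common", d.common), ("specific", d.specific)):
            for S in d.sources:
                rows.append(store[S])
                index.append(f"{S}{block[0]}")
        for S in d.sources:
            rows.append(d.overall(S))
            index.append(S)
        rows.append(d.total_variance)
        index.append("total_variance")
        return pd.DataFrame(rows, index=index, columns=list(d.traits))

    @staticmethod
    def read_shares_csv(path) -> pd.DataFrame:
        """Read a shares table written by ``shares_frame().to_csv`` with
        round-trip float parsing (bit-identical to the written values)."""
        return pd.read_csv(path, index_col=0, float_precision="round_trip")

    def percent_frame(self) -> pd.DataFrame:
        frame = self.shares_frame().drop(index="total_variance")
        return frame.map(_percent)

    def to_text(self) -> str:
        d = self.decomposition
        width = max(12, *(len(t) + 2 for t in d.traits))
        label_w = 44
        out = io.StringIO()
        out.write(f"{self.model_name} Model — selected: {self.selected_label}\n")
        header = "Variable".ljust(label_w) + "".join(t.rjust(width) for t in d.traits)
        out.write(header + "\n")
        blocks = [
            ("Common genetic and environmental factors", "common", "c"),
            ("Specific genetic and environmental factors", "specific", "s"),
            ("Overall contribution of genetic and environmental factors", "overall", ""),
        ]
        for title, block, suffix in blocks:
            out.write(title + "\n")
            for S in d.sources:
                if block == "common":
                    values = d.common[S]
                    label = f"{self._SOURCE_WORD[S]} factors ({S}{suffix})"
                elif block == "specific":
                    values = d.specific[S]
                    label = f"{self._SOURCE_WORD[S]} factors ({S}{suffix})"
                else:
                    values = d.overall(S)
                    label = f"{self._SOURCE_WORD[S]} factors ({S})"
                cells = "".join(f"{_percent(v)}%".rjust(width) for v in values)
                out.write(label.ljust(label_w) + cells + "\n")
        return out.getvalue()


def render_report(
    selected: FittedModel, trace: SelectionTrace, name: str
) -> DecompositionReport:
    """Build the decomposition report for a selected model: the
    standardized three-block percent table and the fit table of every
    candidate (full model first)."""
    decomp = standardize(selected)
    rows = [
        {
            "model": "full",
            "minus2LL": trace.full.minus2ll,
            "df": trace.full.n_free_params,
            "AIC": trace.full.aic,
            "deltaLL": 0.0,
            "deltadf": 0,
            "p": 1.0,
            "kept": trace.selected is trace.full,
        }
    ]
    for step in trace.steps:
        vs_full = step.lrt_vs_full or step.lrt
        rows.append(
            {
                "model": step.label,
                "minus2LL": step.fitted.minus2ll,
                "df": step.fitted.n_free_params,
                "AIC": step.fitted.aic,
                "deltaLL": vs_full.delta_minus2ll,
                "deltadf": vs_full.delta_df,
                "p": vs_full.p_value,
                "kept": step.kept,
            }
        )
    return DecompositionReport(
        model_name=name,
        decomposition=decomp,
        fit_table=pd.DataFrame(rows),
        selected_label=trace.selected_label,
    )
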