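"""Twin structural-equation models: specification, likelihood, ML fitting.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C), non-additive genetic / dominance (D)
and unique environmental (E) sources, identified by the different cross-twin
sharing of each source: MZ co-twins share A fully and DZ co-twins half of
it, C is shared fully by both kinds of pair, D is shared 1/4 by DZ pairs,
and E is never shared.  With p traits ordered (twin 1 traits, twin 2
traits), the model-implied 2p x 2p pair covariance is

    Sigma_z = [[V, W_z], [W_z, V]],   V = sum_S Sigma_S,
    W_z = sum_S kappa(S, z) * Sigma_S,

where for each included source S the trait-level contribution is
``Sigma_S = lambda_S lambda_S' + diag(s_S**2)``: ``lambda_S`` are the
loadings of the single *common* S factor (the independent-pathway part,
zero for univariate models) and ``s_S`` the trait-*specific* S paths.
Variance components are parameterized through unconstrained real paths
whose squares are variances, so every admissible parameter vector yields a
positive-semidefinite structure without constrained optimization.

Means are modelled per individual as intercept + beta_age * age +
beta_sex * sex (definition-variable style covariate adjustment), never by
pre-residualizing the phenotypes.

Fitting minimizes the exact -2 log-likelihood of the pair vectors.  The
likelihood and its analytic gradient are evaluated from per-zygosity
sufficient statistics (cross-moment matrices of phenotypes and covariates),
which makes the cost of one evaluation independent of the number of pairs.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .data import EstimationError, TwinDataset, ValidationError, Zygosity

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFamily",
    "ModelSpec",
    "MeansParameters",
    "PathParameters",
    "SaturatedParameters",
    "FittedModel",
    "VarianceDecomposition",
    "ContractError",
    "LikelihoodError",
    "expected_covariance",
    "minus2_loglik",
    "fit_model",
    "fit_saturated",
    "standardize",
]

LOG_2PI = math.log(2.0 * math.pi)

#: cross-twin sharing coefficient of each variance source, per zygosity
SHARING = {
    "A": {"MZ": 1.0, "DZ": 0.5},
    "C": {"MZ": 1.0, "DZ": 1.0},
    "D": {"MZ": 1.0, "DZ": 0.25},
    "E": {"MZ": 0.0, "DZ": 0.0},
}

_SOURCE_ORDER = ("A", "C", "D", "E")


class ContractError(TypeError):
    """Arguments violate a structural precondition (shape/spec mismatch)."""


class LikelihoodError(RuntimeError):
    """The likelihood is not evaluable (singular model covariance)."""


class ModelFamily(str, enum.Enum):
    UNIVARIATE = "univariate"
    INDEPENDENT_PATHWAY = "independent_pathway"
    SATURATED = "saturated"


# ---------------------------------------------------------------------------
# Specification


@dataclass(frozen=True)
class ModelSpec:
    """Which variance sources are free, and the means model.

    ``common_free[S]`` flags whether the common S factor (all p loadings) is
    free; ``specific_free[S]`` flags each trait-specific S path.  Masked
    entries are fixed to exactly zero.  E is always included; C and D are
    never jointly included (not identifiable from twins reared together).
    """

    family: ModelFamily
    traits: tuple[str, ...]
    sources: tuple[str, ...]
    common_free: Mapping[str, bool]
    specific_free: Mapping[str, tuple[bool, ...]]
    adjust_age: bool = True
    adjust_sex: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        srcs = tuple(s for s in _SOURCE_ORDER if s in self.sources)
        if set(srcs) != set(self.sources):
            raise ValidationError(f"unknown source(s) in {self.sources}")
        object.__setattr__(self, "sources", srcs)
        p = len(self.traits)
        if self.family is ModelFamily.SATURATED:
            return
        if "E" not in srcs:
            raise ValidationError("E must always be included")
        if "C" in srcs and "D" in srcs:
            raise ValidationError("C and D are not jointly identifiable")
        cf = {S: bool(self.common_free.get(S, False)) for S in srcs}
        sf = {}
        for S in srcs:
            flags = self.specific_free.get(S, (False,) * p)
            if len(flags) != p:
                raise ContractError(f"specific_free[{S}] must have length {p}")
            sf[S] = tuple(bool(b) for b in flags)
        object.__setattr__(self, "common_free", cf)
        object.__setattr__(self, "specific_free", sf)
        if self.family is ModelFamily.UNIVARIATE:
            if p != 1:
                raise ValidationError("univariate spec requires exactly one trait")
            if any(cf.values()):
                raise ValidationError("univariate spec has no common factors")
        if self.family is ModelFamily.INDEPENDENT_PATHWAY and any(cf.values()) and p < 3:
            raise ValidationError("independent-pathway common factors need >=3 traits")

    # -- constructors ------------------------------------------------------

    @classmethod
    def univariate(
        cls,
        trait: str,
        sources: Sequence[str] = ("A", "C", "E"),
        adjust_age: bool = True,
        adjust_sex: bool = True,
    ) -> "ModelSpec":
        srcs = tuple(sources)
        return cls(
            family=ModelFamily.UNIVARIATE,
            traits=(trait,),
            sources=srcs,
            common_free={},
            specific_free={S: (True,) for S in srcs},
            adjust_age=adjust_age,
            adjust_sex=adjust_sex,
        )

    @classmethod
    def independent_pathway(
        cls,
        traits: Sequence[str],
        sources: Sequence[str] = ("A", "C", "E"),
        adjust_age: bool = True,
        adjust_sex: bool = True,
    ) -> "ModelSpec":
        """Full independent-pathway model: one common factor plus one
        trait-specific path per source."""
        traits = tuple(traits)
        srcs = tuple(sources)
        return cls(
            family=ModelFamily.INDEPENDENT_PATHWAY,
            traits=traits,
            sources=srcs,
            common_free={S: True for S in srcs},
            specific_free={S: (True,) * len(traits) for S in srcs},
            adjust_age=adjust_age,
            adjust_sex=adjust_sex,
        )

    @classmethod
    def saturated(
        cls, traits: Sequence[str], adjust_age: bool = True, adjust_sex: bool = True
    ) -> "ModelSpec":
        return cls(
            family=ModelFamily.SATURATED,
            traits=tuple(traits),
            sources=(),
            common_free={},
            specific_free={},
            adjust_age=adjust_age,
            adjust_sex=adjust_sex,
        )

    # -- structure ---------------------------------------------------------

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_free_params(self) -> int:
        p = self.n_traits
        n_means = p * (1 + self.adjust_age + self.adjust_sex)
        if self.family is ModelFamily.SATURATED:
            # per-zygosity free means (2p each) + shared slopes + two free
            # symmetric 2p x 2p covariances
            return 4 * p + p * (self.adjust_age + self.adjust_sex) + 2 * p * (2 * p + 1)
        n = sum(p for S in self.sources if self.common_free[S])
        n += sum(sum(self.specific_free[S]) for S in self.sources)
        return n + n_means

    def drop_common(self, source: str) -> "ModelSpec":
        if not self.common_free.get(source, False):
            raise ContractError(f"common {source} factor is not free")
        cf = dict(self.common_free)
        cf[source] = False
        return dataclasses.replace(self, common_free=cf)

    def drop_specific(self, source: str, trait_index: int) -> "ModelSpec":
        if not self.specific_free[source][trait_index]:
            raise ContractError(f"specific {source} path {trait_index} is not free")
        sf = dict(self.specific_free)
        flags = list(sf[source])
        flags[trait_index] = False
        sf[source] = tuple(flags)
        return dataclasses.replace(self, specific_free=sf)

    def is_nested_in(self, full: "ModelSpec") -> bool:
        """True when every free parameter of self is free in ``full``."""
        if self.traits != full.traits:
            return False
        if self.adjust_age > full.adjust_age or self.adjust_sex > full.adjust_sex:
            return False
        if full.family is ModelFamily.SATURATED:
            return self.family is not ModelFamily.SATURATED
        if self.family is ModelFamily.SATURATED or self.family is not full.family:
            return False
        if not set(self.sources) <= set(full.sources):
            return False
        for S in self.sources:
            if self.common_free[S] and not full.common_free[S]:
                return False
            for ours, theirs in zip(self.specific_free[S], full.specific_free[S]):
                if ours and not theirs:
                    return False
        return True

    # -- JSON --------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "traits": list(self.traits),
            "sources": list(self.sources),
            "common_free": dict(self.common_free),
            "specific_free": {S: list(f) for S, f in self.specific_free.items()},
            "adjust_age": self.adjust_age,
            "adjust_sex": self.adjust_sex,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            family=ModelFamily(d["family"]),
            traits=tuple(d["traits"]),
            sources=tuple(d["sources"]),
            common_free=dict(d.get("common_free", {})),
            specific_free={S: tuple(f) for S, f in d.get("specific_free", {}).items()},
            adjust_age=bool(d.get("adjust_age", True)),
            adjust_sex=bool(d.get("adjust_sex", True)),
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class MeansParameters:
    """Per-trait intercept and covariate slopes of the means model."""

    intercept: np.ndarray  # (p,), trait units
    beta_age: np.ndarray  # (p,), trait units per year
    beta_sex: np.ndarray  # (p,), trait units (female minus male)

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, float)
        self.beta_age = np.asarray(self.beta_age, float)
        self.beta_sex = np.asarray(self.beta_sex, float)


@dataclass
class PathParameters:
    """Raw path coefficients for a structured model.

    ``loadings[S]`` is the length-p common-factor loading vector of source S
    (all zero when the common factor is masked or the model is univariate);
    ``specifics[S]`` the length-p trait-specific paths.  Masked entries are
    exactly 0.  Sign convention after fitting: the first entry of each free
    loading vector and every specific path are >= 0.
    """

    loadings: dict[str, np.ndarray]
    specifics: dict[str, np.ndarray]
    means: MeansParameters

    def __post_init__(self) -> None:
        self.loadings = {S: np.asarray(v, float) for S, v in self.loadings.items()}
        self.specifics = {S: np.asarray(v, float) for S, v in self.specifics.items()}

    def copy(self) -> "PathParameters":
        return PathParameters(
            loadings={S: v.copy() for S, v in self.loadings.items()},
            specifics={S: v.copy() for S, v in self.specifics.items()},
            means=MeansParameters(
                self.means.intercept.copy(),
                self.means.beta_age.copy(),
                self.means.beta_sex.copy(),
            ),
        )


@dataclass
class SaturatedParameters:
    """Free per-zygosity means and covariances of the saturated model."""

    mean_by_zygosity: dict[str, np.ndarray]  # z -> (2p,) intercepts per element
    beta_age: np.ndarray  # (p,), shared across twins and zygosity
    beta_sex: np.ndarray  # (p,)
    covariance_by_zygosity: dict[str, np.ndarray]  # z -> (2p, 2p)


@dataclass
class FittedModel:
    """A converged (or best-effort) maximum-likelihood fit."""

    spec: ModelSpec
    params: PathParameters | SaturatedParameters
    minus2ll: float
    n_free_params: int
    aic: float
    converged: bool
    n_starts_used: int = 1
    best_start_seed: int = 0


def _check_conform(params: PathParameters, spec: ModelSpec) -> None:
    p = spec.n_traits
    for S in spec.sources:
        for store, name in ((params.loadings, "loadings"), (params.specifics, "specifics")):
            v = store.get(S)
            if v is None or v.shape != (p,):
                raise ContractError(f"params.{name}[{S!r}] must have shape ({p},)")
    if params.means.intercept.shape != (p,):
        raise ContractError(f"means.intercept must have shape ({p},)")


def canonicalize(params: PathParameters, spec: ModelSpec) -> PathParameters:
    """Resolve sign indeterminacies: variance contributions depend only on
    squared paths, so flip each free loading vector to make its first entry
    nonnegative and take specific paths as their absolute values."""
    out = params.copy()
    for S in spec.sources:
        if spec.common_free.get(S, False) and out.loadings[S][0] < 0:
            out.loadings[S] = -out.loadings[S]
        out.specifics[S] = np.abs(out.specifics[S])
    return out


# ---------------------------------------------------------------------------
# Moment structure


def _trait_sigma(params: PathParameters, S: str) -> np.ndarray:
    lam = params.loadings[S]
    s = params.specifics[S]
    return np.outer(lam, lam) + np.diag(s * s)


def expected_covariance(
    params: PathParameters, spec: ModelSpec, zygosity: Zygosity | str
) -> np.ndarray:
    """Model-implied 2p x 2p covariance of a twin pair's stacked phenotype
    vector (twin 1 traits, then twin 2 traits), for the given zygosity."""
    _check_conform(params, spec)
    z = Zygosity(zygosity).value
    p = spec.n_traits
    V = np.zeros((p, p))
    W = np.zeros((p, p))
    for S in spec.sources:
        sig = _trait_sigma(params, S)
        V += sig
        W += SHARING[S][z] * sig
    return np.block([[V, W], [W, V]])


# ---------------------------------------------------------------------------
# Sufficient statistics and likelihood

_COVS = ("one", "age", "sex")


class PairStats:
    """Per-zygosity cross-moment statistics of pair vectors and covariates.

    Pairs are put into a canonical within-pair order (lexicographic on the
    twin's phenotypes, age, sex) before accumulation; the model is
    twin-exchangeable, so this changes nothing mathematically but makes the
    likelihood bit-for-bit invariant to swapping twins within a pair.
    """

    def __init__(self, dataset: TwinDataset, traits: Sequence[str]):
        traits = tuple(traits)
        y, ages, sexes, zyg = dataset.arrays(traits)
        if not (
            np.isfinite(y).all() and np.isfinite(ages).all() and np.isfinite(sexes).all()
        ):
            raise EstimationError(
                "dataset must be complete-case for the model's traits and covariates"
            )
        n, _, p = y.shape
        key = np.concatenate([y, ages[:, :, None], sexes[:, :, None]], axis=2)
        k1, k2 = key[:, 0, :], key[:, 1, :]
        neq = k1 != k2
        first = np.argmax(neq, axis=1)
        rows = np.arange(n)
        swap = neq.any(axis=1) & (k1[rows, first] > k2[rows, first])
        y[swap] = y[swap][:, ::-1]
        ages[swap] = ages[swap][:, ::-1]
        sexes[swap] = sexes[swap][:, ::-1]

        # pooled covariate centers (per-pair symmetric sums keep them
        # bitwise swap-invariant); optimization runs on centered covariates
        self.age_center = float(np.sum(ages[:, 0] + ages[:, 1]) / (2 * n))
        self.sex_center = float(np.sum(sexes[:, 0] + sexes[:, 1]) / (2 * n))
        ages = ages - self.age_center
        sexes = sexes - self.sex_center

        self.p = p
        self.groups: dict[str, dict] = {}
        for group in ("MZ", "DZ"):
            m = zyg == group
            ng = int(m.sum())
            if ng == 0:
                continue
            Y = np.concatenate([y[m, 0, :], y[m, 1, :]], axis=1)  # (ng, 2p)
            D = np.stack(
                [
                    np.ones((ng, 2 * p)),
                    np.repeat(ages[m], p, axis=1),
                    np.repeat(sexes[m], p, axis=1),
                ]
            )  # (3, ng, 2p)
            self.groups[group] = {
                "n": ng,
                "Syy": Y.T @ Y,
                "Y": np.einsum("nj,cnl->cjl", Y, D, optimize=True),
                "G": np.einsum("cnj,enl->cejl", D, D, optimize=True),
            }

    def mean_vectors(self, means: MeansParameters) -> np.ndarray:
        """Coefficient row per covariate channel (one, age, sex), length 2p.

        The intercept paired with centered covariates is the mean at the
        pooled covariate centers."""
        centered_intercept = (
            means.intercept
            + means.beta_age * self.age_center
            + means.beta_sex * self.sex_center
        )
        return np.stack(
            [
                np.tile(centered_intercept, 2),
                np.tile(means.beta_age, 2),
                np.tile(means.beta_sex, 2),
            ]
        )


def _group_nll(sigma: np.ndarray, g: dict, v: np.ndarray, want_grad: bool):
    """-2 log-likelihood contribution of one zygosity group (and, when
    requested, the matrices needed for its analytic gradient).

    ``v`` holds the covariate coefficient rows (one, age, sex) as produced
    by :meth:`PairStats.mean_vectors`.
    """
    n, d = g["n"], sigma.shape[0]
    try:
        cf = cho_factor(sigma, lower=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise LikelihoodError(f"singular model covariance: {exc}") from None
    diag = np.diagonal(cf[0])
    if np.any(diag <= 0):
        raise LikelihoodError("singular model covariance")
    logdet = 2.0 * float(np.sum(np.log(diag)))
    M = np.einsum("cjl,cl->jl", g["Y"], v)
    Q = np.einsum("cejl,cj,el->jl", g["G"], v, v)
    C = g["Syy"] - M - M.T + Q
    P = cho_solve(cf, np.eye(d))
    value = n * (d * LOG_2PI + logdet) + float(np.sum(P * C))
    if not want_grad:
        return value, None
    Gmat = n * P - P @ C @ P
    # d(-2LL)/dv rows: -2 diag(P Y_c) + 2 sum_e (P o G_ce) v_e
    mean_grad = -2.0 * np.einsum("jl,clj->cj", P, g["Y"]) + 2.0 * np.einsum(
        "jl,cejl,el->cj", P, g["G"], v
    )
    return value, (Gmat, mean_grad)


def minus2_loglik(
    params: PathParameters, spec: ModelSpec, dataset: TwinDataset
) -> float:
    """Exact -2 log-likelihood of the pair vectors under the structured
    model: ``sum_pairs [2p log 2pi + log det Sigma_z + r' Sigma_z^-1 r]``
    with zygosity-specific covariance and per-individual means."""
    _check_conform(params, spec)
    stats = PairStats(dataset, spec.traits)
    v = stats.mean_vectors(params.means)
    total = 0.0
    for group, g in stats.groups.items():
        sigma = expected_covariance(params, spec, group)
        value, _ = _group_nll(sigma, g, v, want_grad=False)
        total += value
    return total


# ---------------------------------------------------------------------------
# Parameter packing


class _Packing:
    """Maps between a flat optimizer vector and PathParameters.

    The optimizer's intercept variable is the trait mean *at the pooled
    covariate centers*; pack/unpack convert to and from the raw intercept,
    which keeps the optimization well-conditioned without changing the
    reported parameters.
    """

    def __init__(self, spec: ModelSpec, age_center: float = 0.0, sex_center: float = 0.0):
        self.spec = spec
        self.age_center = age_center
        self.sex_center = sex_center
        p = spec.n_traits
        self.slices: dict = {}
        idx = 0
        for S in spec.sources:
            if spec.common_free[S]:
                self.slices[("loading", S)] = slice(idx, idx + p)
                idx += p
            k = sum(spec.specific_free[S])
            if k:
                self.slices[("specific", S)] = slice(idx, idx + k)
                idx += k
        self.slices["intercept"] = slice(idx, idx + p)
        idx += p
        if spec.adjust_age:
            self.slices["beta_age"] = slice(idx, idx + p)
            idx += p
        if spec.adjust_sex:
            self.slices["beta_sex"] = slice(idx, idx + p)
            idx += p
        self.n_free = idx

    def unpack(self, x: np.ndarray) -> PathParameters:
        spec = self.spec
        p = spec.n_traits
        loadings, specifics = {}, {}
        for S in spec.sources:
            lam = np.zeros(p)
            if ("loading", S) in self.slices:
                lam = np.array(x[self.slices[("loading", S)]])
            s = np.zeros(p)
            if ("specific", S) in self.slices:
                s[np.array(spec.specific_free[S])] = x[self.slices[("specific", S)]]
            loadings[S], specifics[S] = lam, s
        zeros = np.zeros(p)
        beta_age = np.array(x[self.slices["beta_age"]]) if spec.adjust_age else zeros.copy()
        beta_sex = np.array(x[self.slices["beta_sex"]]) if spec.adjust_sex else zeros.copy()
        means = MeansParameters(
            intercept=np.array(x[self.slices["intercept"]])
            - beta_age * self.age_center
            - beta_sex * self.sex_center,
            beta_age=beta_age,
            beta_sex=beta_sex,
        )
        return PathParameters(loadings=loadings, specifics=specifics, means=means)

    def pack(self, params: PathParameters) -> np.ndarray:
        spec = self.spec
        x = np.zeros(self.n_free)
        for S in spec.sources:
            if ("loading", S) in self.slices:
                x[self.slices[("loading", S)]] = params.loadings[S]
            if ("specific", S) in self.slices:
                mask = np.array(spec.specific_free[S])
                x[self.slices[("specific", S)]] = params.specifics[S][mask]
        x[self.slices["intercept"]] = (
            params.means.intercept
            + params.means.beta_age * self.age_center
            + params.means.beta_sex * self.sex_center
        )
        if spec.adjust_age:
            x[self.slices["beta_age"]] = params.means.beta_age
        if spec.adjust_sex:
            x[self.slices["beta_sex"]] = params.means.beta_sex
        return x

    def gradient(
        self,
        params: PathParameters,
        H: dict[str, np.ndarray],
        mean_grad: np.ndarray,
    ) -> np.ndarray:
        """Assemble d(-2LL)/dx from per-source trait-block matrices H[S]
        (= d(-2LL)/dSigma_S in trace sense) and the covariate-row gradient
        matrix (3, 2p)."""
        spec = self.spec
        p = spec.n_traits
        g = np.zeros(self.n_free)
        for S in spec.sources:
            if ("loading", S) in self.slices:
                g[self.slices[("loading", S)]] = 2.0 * H[S] @ params.loadings[S]
            if ("specific", S) in self.slices:
                mask = np.array(spec.specific_free[S])
                g[self.slices[("specific", S)]] = (
                    2.0 * params.specifics[S] * np.diagonal(H[S])
                )[mask]
        folded = mean_grad[:, :p] + mean_grad[:, p:]
        g[self.slices["intercept"]] = folded[0]
        if spec.adjust_age:
            g[self.slices["beta_age"]] = folded[1]
        if spec.adjust_sex:
            g[self.slices["beta_sex"]] = folded[2]
        return g


def _objective(x: np.ndarray, packing: _Packing, stats: PairStats):
    spec = packing.spec
    params = packing.unpack(x)
    v = stats.mean_vectors(params.means)
    p = spec.n_traits
    sig_S = {S: _trait_sigma(params, S) for S in spec.sources}
    V = sum(sig_S.values())
    total = 0.0
    H = {S: np.zeros((p, p)) for S in spec.sources}
    mean_grad = np.zeros((3, 2 * p))
    try:
        for group, g in stats.groups.items():
            W = sum(SHARING[S][group] * sig_S[S] for S in spec.sources)
            sigma = np.empty((2 * p, 2 * p))
            sigma[:p, :p] = V
            sigma[p:, p:] = V
            sigma[:p, p:] = W
            sigma[p:, :p] = W
            value, extras = _group_nll(sigma, g, v, want_grad=True)
            total += value
            Gmat, mg = extras
            B = Gmat[:p, :p] + Gmat[p:, p:]
            Bx = Gmat[:p, p:] + Gmat[p:, :p]
            for S in spec.sources:
                H[S] += B + SHARING[S][group] * Bx
            mean_grad += mg
    except LikelihoodError:
        return 1e15, np.zeros(packing.n_free)
    return total, packing.gradient(params, H, mean_grad)


# ---------------------------------------------------------------------------
# Fitting


def _start_points(
    packing: _Packing,
    stats: PairStats,
    dataset_stats: tuple[np.ndarray, np.ndarray],
    n_starts: int,
    seed: int,
    init: PathParameters | None,
) -> list[np.ndarray]:
    """Deterministic multi-start initial vectors.

    Start 0 splits each trait's sample variance equally over that trait's
    free paths and sets the means to the pooled sample means; later starts
    scatter paths multiplicatively and randomize loading signs.
    """
    spec = packing.spec
    p = spec.n_traits
    trait_var, trait_mean = dataset_stats
    k = np.zeros(p)
    for S in spec.sources:
        if spec.common_free[S]:
            k += 1.0
        k += np.array(spec.specific_free[S], float)
    k = np.maximum(k, 1.0)
    base_path = np.sqrt(trait_var / k)

    def build(scale_lam, scale_s, mean_shift, betas) -> np.ndarray:
        params = packing.unpack(np.zeros(packing.n_free))
        for S in spec.sources:
            if spec.common_free[S]:
                params.loadings[S] = base_path * scale_lam[S]
            params.specifics[S] = base_path * scale_s[S] * np.array(
                spec.specific_free[S], float
            )
        params.means = MeansParameters(
            intercept=trait_mean + mean_shift,
            beta_age=betas[0] if spec.adjust_age else np.zeros(p),
            beta_sex=betas[1] if spec.adjust_sex else np.zeros(p),
        )
        return packing.pack(params)

    starts = []
    if init is not None:
        starts.append(packing.pack(init))
    if len(starts) < n_starts:
        ones = {S: np.ones(p) for S in spec.sources}
        starts.append(build(ones, ones, np.zeros(p), (np.zeros(p), np.zeros(p))))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        scale_lam = {
            S: rng.uniform(0.5, 1.5, p) * rng.choice([-1.0, 1.0], p)
            for S in spec.sources
        }
        scale_s = {S: rng.uniform(0.5, 1.5, p) for S in spec.sources}
        mean_shift = rng.normal(0.0, 0.1, p) * np.sqrt(trait_var)
        betas = (rng.normal(0.0, 0.05, p), rng.normal(0.0, 0.05, p))
        starts.append(build(scale_lam, scale_s, mean_shift, betas))
    return starts


def fit_model(
    dataset: TwinDataset,
    spec: ModelSpec,
    *,
    n_starts: int = 10,
    seed: int = 0,
    init: PathParameters | None = None,
    maxiter: int = 1500,
    ftol: float = 1e-10,
    gtol: float = 1e-5,
) -> FittedModel:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B) minimization of
    the exact -2 log-likelihood from ``n_starts`` deterministic starting
    points; the best optimum is kept and signs are canonicalized.

    Never raises on optimization failure: if every start fails the
    convergence tolerance the best point is returned with
    ``converged=False``.
    """
    if spec.family is ModelFamily.SATURATED:
        return fit_saturated(
            dataset, spec.traits, adjust_age=spec.adjust_age, adjust_sex=spec.adjust_sex
        )
    missing = [t for t in spec.traits if t not in dataset.trait_names]
    if missing:
        raise ContractError(f"dataset lacks trait(s): {', '.join(missing)}")
    stats = PairStats(dataset, spec.traits)
    for group in ("MZ", "DZ"):
        if stats.groups.get(group, {"n": 0})["n"] < 2:
            raise EstimationError(f"need >=2 complete {group} pairs")
    y, _, _, _ = dataset.arrays(spec.traits)
    flat = y.reshape(-1, spec.n_traits)
    dataset_stats = (flat.var(axis=0), flat.mean(axis=0))
    packing = _Packing(spec, stats.age_center, stats.sex_center)
    starts = _start_points(packing, stats, dataset_stats, n_starts, seed, init)

    best = None
    best_idx = 0
    any_converged = False
    for idx, x0 in enumerate(starts):
        res = optimize.minimize(
            _objective,
            x0,
            args=(packing, stats),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12 or (
            res.fun < best.fun + 1e-12 and res.success and not best.success
        ):
            best, best_idx = res, idx
        any_converged = any_converged or bool(res.success)
    if best is None:  # pragma: no cover - defensive
        raise EstimationError("all optimization starts failed")
    params = canonicalize(packing.unpack(best.x), spec)
    n_free = packing.n_free
    return FittedModel(
        spec=spec,
        params=params,
        minus2ll=float(best.fun),
        n_free_params=n_free,
        aic=float(best.fun) + 2.0 * n_free,
        converged=any_converged,
        n_starts_used=len(starts),
        best_start_seed=seed + best_idx,
    )


def fit_saturated(
    dataset: TwinDataset,
    traits: Sequence[str],
    *,
    adjust_age: bool = True,
    adjust_sex: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> FittedModel:
    """Unstructured reference model: free per-zygosity mean vectors and
    2p x 2p covariances, with shared age/sex slopes when adjusted.

    Fitted by alternating exact conditional maximizations (GLS for the
    means, the residual second-moment matrix for each covariance); with no
    covariates this converges in one step to the closed-form Gaussian MLE
    (per-zygosity sample means and 1/n sample covariances).  Used as the
    likelihood ceiling for structured models.
    """
    traits = tuple(traits)
    spec = ModelSpec.saturated(traits, adjust_age=adjust_age, adjust_sex=adjust_sex)
    stats = PairStats(dataset, traits)  # validates complete-case
    y, ages, sexes, zyg = dataset.arrays(traits)
    p = len(traits)
    d = 2 * p
    groups = [g for g in ("MZ", "DZ") if g in stats.groups]
    if len(groups) < 2:
        raise EstimationError("saturated fit needs both zygosity groups")

    # design tensor per group: X[k] maps the unknown vector u =
    # (alpha_MZ, alpha_DZ, [beta_age], [beta_sex]) to the pair's mean vector
    q = 2 * d + p * (adjust_age + adjust_sex)
    Xs, Ys, ns = {}, {}, {}
    tile = np.zeros((d, p))
    for i in range(p):
        tile[i, i] = 1.0
        tile[p + i, i] = 1.0
    for gi, group in enumerate(groups):
        m = zyg == group
        ng = int(m.sum())
        Y = np.concatenate([y[m, 0, :], y[m, 1, :]], axis=1)
        X = np.zeros((ng, d, q))
        X[:, :, gi * d : (gi + 1) * d] = np.eye(d)
        col = 2 * d
        if adjust_age:
            da = np.repeat(ages[m], p, axis=1)  # (ng, 2p)
            X[:, :, col : col + p] = da[:, :, None] * tile[None, :, :]
            col += p
        if adjust_sex:
            ds = np.repeat(sexes[m], p, axis=1)
            X[:, :, col : col + p] = ds[:, :, None] * tile[None, :, :]
        Xs[group], Ys[group], ns[group] = X, Y, ng

    # initialize covariances from per-group moments about the group mean
    sig = {}
    for group in groups:
        R0 = Ys[group] - Ys[group].mean(axis=0)
        sig[group] = R0.T @ R0 / ns[group] + 1e-8 * np.eye(d)

    prev = np.inf
    converged = False
    u = np.zeros(q)
    for _ in range(max_iter):
        A = np.zeros((q, q))
        b = np.zeros(q)
        P = {}
        for group in groups:
            try:
                P[group] = np.linalg.inv(sig[group])
            except np.linalg.LinAlgError:
                raise LikelihoodError("singular saturated covariance") from None
            X, Y = Xs[group], Ys[group]
            A += np.einsum("njq,jl,nlr->qr", X, P[group], X, optimize=True)
            b += np.einsum("njq,jl,nl->q", X, P[group], Y, optimize=True)
        u = np.linalg.solve(A, b)
        value = 0.0
        for group in groups:
            R = Ys[group] - np.einsum("njq,q->nj", Xs[group], u)
            sig[group] = R.T @ R / ns[group]
            sign, logdet = np.linalg.slogdet(sig[group])
            if sign <= 0:
                raise LikelihoodError("singular saturated covariance")
            value += ns[group] * (d * LOG_2PI + logdet + d)
        if abs(prev - value) <= tol * max(1.0, abs(value)):
            converged = True
            prev = value
            break
        prev = value

    alpha = {group: u[gi * d : (gi + 1) * d] for gi, group in enumerate(groups)}
    col = 2 * d
    beta_age = u[col : col + p] if adjust_age else np.zeros(p)
    col += p if adjust_age else 0
    beta_sex = u[col : col + p] if adjust_sex else np.zeros(p)
    params = SaturatedParameters(
        mean_by_zygosity=alpha,
        beta_age=beta_age,
        beta_sex=beta_sex,
        covariance_by_zygosity=sig,
    )
    n_free = spec.n_free_params
    return FittedModel(
        spec=spec,
        params=params,
        minus2ll=float(prev),
        n_free_params=n_free,
        aic=float(prev) + 2.0 * n_free,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class VarianceDecomposition:
    """Standardized variance shares per trait.

    ``common[S][i]`` and ``specific[S][i]`` are the proportions of trait i's
    total variance carried by the common S factor and the trait-specific S
    path; per trait they sum to 1 across all included sources.
    """

    traits: tuple[str, ...]
    common: dict[str, np.ndarray]
    specific: dict[str, np.ndarray]
    total_variance: np.ndarray

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self.common.keys())

    def overall(self, source: str) -> np.ndarray:
        """Total share of one source: common + specific contributions."""
        return self.common[source] + self.specific[source]

    def share_sum(self) -> np.ndarray:
        total = np.zeros(len(self.traits))
        for S in self.sources:
            total += self.overall(S)
        return total


def standardize(model: FittedModel) -> VarianceDecomposition:
    """Standardize fitted paths into variance shares: per trait i,
    V_i = sum_S (lambda_Si^2 + s_Si^2); the common share of source S is
    lambda_Si^2 / V_i and the specific share s_Si^2 / V_i."""
    if not isinstance(model.params, PathParameters):
        raise ContractError("standardize requires a structured (path) model")
    if not model.converged:
        raise EstimationError("cannot standardize a non-converged model")
    spec = model.spec
    p = spec.n_traits
    common_var = {S: model.params.loadings[S] ** 2 for S in spec.sources}
    specific_var = {S: model.params.specifics[S] ** 2 for S in spec.sources}
    V = np.zeros(p)
    for S in spec.sources:
        V += common_var[S] + specific_var[S]
    if np.any(V <= 0):
        bad = [spec.traits[i] for i in range(p) if V[i] <= 0]
        raise EstimationError(f"zero total variance for trait(s): {', '.join(bad)}")
    return VarianceDecomposition(
        traits=spec.traits,
        common={S: common_var[S] / V for S in spec.sources},
        specific={S: specific_var[S] / V for S in spec.sources},
        total_variance=V,
    )
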