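"""Null-distribution simulation and synthetic community generation.

Scanning all n(n-1) directed odds ratios of a species assemblage invites
spurious "substantial" associations. :func:`simulate_null` quantifies
that risk: species are generated independently (no real associations) at
chosen prevalences and survey counts — optionally with per-species site
random intercepts to mimic repeated surveys — and each replicate tallies
how many directed odds ratios exceed the indication threshold or fall
below the contraindication threshold, with and without statistical
significance. Matched to a study's prevalence profile and survey count,
the median spurious counts say how many of the observed substantial
associations independence alone could produce.

:func:`generate_community` is the converse tool: it plants known
associations. For a designated pair it draws presence jointly from the
2x2 distribution that realises the requested marginal prevalences and
directed odds ratio (the co-occurrence cell is determined linearly by
the directed OR given the margins; the classical cross-product OR is
also supported, where the cell solves a quadratic and the root inside
the Frechet bounds is taken). Remaining species are independent. Site
random intercepts shift every species' probability on the logit scale,
independently per species by default, with an optional shared component
representing common habitat responses. Everything is deterministic under
the supplied seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .assemble import AssemblyConfig
from .estimation import SurveyTable, estimate_all_pairs

__all__ = [
    "NullSimConfig",
    "NullSimResult",
    "PlantedAssociation",
    "SyntheticCommunitySpec",
    "simulate_null",
    "generate_community",
    "cooccurrence_cell",
]


# ---------------------------------------------------------------------------
# 2x2 inversion: co-occurrence cell from margins + odds ratio


def cooccurrence_cell(
    p_a: float,
    p_b: float,
    odds_ratio: float,
    or_type: Literal["directed", "cross"] = "directed",
    *,
    clip: bool = False,
) -> float:
    """P(both present) realising given margins and odds ratio.

    ``or_type="directed"``: ``odds_ratio`` is the directed OR of species
    A indicated by B — odds(A | B present) / odds(A). Then
    P(A | B) = OR * odds_A / (1 + OR * odds_A) and the cell is
    p_b * P(A | B), linear in the cell.

    ``or_type="cross"``: the symmetric cross-product ratio; the cell
    solves (psi - 1) c^2 - [1 + (p_a + p_b)(psi - 1)] c + psi p_a p_b = 0
    and the root inside the Frechet bounds is selected.

    Raises an error when no joint distribution with these margins attains
    the ratio, unless ``clip`` is set (used for site-shifted margins,
    where the cell is clamped to the nearest attainable value).
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("margins must be strictly inside (0, 1)")
    if not odds_ratio > 0.0 or math.isinf(odds_ratio):
        raise ValueError("odds ratio must be finite and positive")
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    if or_type == "directed":
        odds_a = p_a / (1.0 - p_a)
        cond = odds_ratio * odds_a / (1.0 + odds_ratio * odds_a)
        c = p_b * cond
    elif or_type == "cross":
        psi = odds_ratio
        if psi == 1.0:
            c = p_a * p_b
        else:
            s = 1.0 + (p_a + p_b) * (psi - 1.0)
            disc = s * s - 4.0 * psi * (psi - 1.0) * p_a * p_b
            c = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    else:
        raise ValueError(f"or_type must be 'directed' or 'cross', got {or_type!r}")
    if c < lo - 1e-12 or c > hi + 1e-12:
        if clip:
            return float(min(max(c, lo), hi))
        raise ValueError(
            f"no 2x2 distribution with margins ({p_a}, {p_b}) attains "
            f"{or_type} odds ratio {odds_ratio} (cell {c:.4f} outside "
            f"[{lo:.4f}, {hi:.4f}])"
        )
    return float(min(max(c, lo), hi))


# ---------------------------------------------------------------------------
# synthetic community generator


@dataclass(frozen=True)
class PlantedAssociation:
    """A true pairwise association: ``target`` indicated by ``predictor``.

    ``odds_ratio`` is the directed OR of the target given the predictor
    (or the cross-product ratio when ``or_type="cross"``), holding
    conditionally on the site effects.
    """

    target: str
    predictor: str
    odds_ratio: float
    or_type: Literal["directed", "cross"] = "directed"


@dataclass
class SyntheticCommunitySpec:
    """Design of a synthetic survey programme with known associations."""

    prevalences: dict[str, float] | pd.Series
    associations: Sequence[PlantedAssociation] = ()
    n_sites: int = 200
    surveys_per_site: int = 4
    sigma_site: float = 0.0
    site_effect_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> pd.Series:
        prev = pd.Series(self.prevalences, dtype=float)
        if not ((prev > 0) & (prev < 1)).all():
            raise ValueError("all prevalences must be strictly inside (0, 1)")
        used: set[str] = set()
        for a in self.associations:
            if a.target == a.predictor:
                raise ValueError("an association needs two distinct species")
            for s in (a.target, a.predictor):
                if s not in prev.index:
                    raise ValueError(f"association references unknown species {s!r}")
                if s in used:
                    raise ValueError(
                        f"species {s!r} appears in more than one planted association"
                    )
                used.add(s)
            # fail fast if the base margins cannot attain the ratio
            cooccurrence_cell(
                prev[a.target], prev[a.predictor], a.odds_ratio, a.or_type
            )
        if self.sigma_site < 0:
            raise ValueError("sigma_site must be non-negative")
        if not 0.0 <= self.site_effect_correlation <= 1.0:
            raise ValueError("site_effect_correlation must be in [0, 1]")
        if self.n_sites < 1 or self.surveys_per_site < 1:
            raise ValueError("need at least one site and one survey per site")
        return prev


def _site_intercepts(
    rng: np.random.Generator, n_sites: int, n_species: int, sigma: float, rho: float
) -> np.ndarray:
    """Per-site, per-species logit intercepts, N(0, sigma^2).

    ``rho`` mixes in a component shared by all species at a site
    (a common habitat-suitability response); rho = 0 gives independent
    effects per species.
    """
    if sigma == 0.0:
        return np.zeros((n_sites, n_species))
    own = rng.standard_normal((n_sites, n_species))
    if rho > 0.0:
        shared = rng.standard_normal((n_sites, 1))
        own = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
    return sigma * own


def generate_community(spec: SyntheticCommunitySpec) -> SurveyTable:
    """Draw a survey table with the spec's prevalences and associations.

    Associated pairs are drawn jointly from the 2x2 distribution holding
    their directed odds ratio at the specified value conditionally on the
    site effects (the cell is clamped to the Frechet bounds at sites whose
    shifted margins cannot attain it); all other species are independent
    Bernoulli draws. Identical seeds give identical tables.
    """
    prev = spec.validate()
    names = list(prev.index)
    n_species = len(names)
    n = spec.n_sites * spec.surveys_per_site
    site_of_survey = np.repeat(np.arange(spec.n_sites), spec.surveys_per_site)
    rng = np.random.default_rng(spec.seed)
    u = _site_intercepts(
        rng, spec.n_sites, n_species, spec.sigma_site, spec.site_effect_correlation
    )
    base_logit = logit(prev.to_numpy())
    p_site = expit(base_logit[None, :] + u)  # (n_sites, n_species)
    p_survey = p_site[site_of_survey, :]  # (n_surveys, n_species)

    X = (rng.random((n, n_species)) < p_survey).astype(np.int8)

    col = {s: k for k, s in enumerate(names)}
    for a in spec.associations:
        it, ip = col[a.target], col[a.predictor]
        pa = p_survey[:, it]
        pb = p_survey[:, ip]
        c = np.array(
            [
                cooccurrence_cell(float(x), float(y), a.odds_ratio, a.or_type, clip=True)
                for x, y in zip(pa, pb)
            ]
        )
        # joint cell probabilities (both, target only, predictor only, neither)
        probs = np.stack([c, pa - c, pb - c, 1.0 - pa - pb + c], axis=1)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        draw = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        cat = (draw[:, None] >= cum).sum(axis=1)  # 0..3
        X[:, it] = (cat <= 1).astype(np.int8)
        X[:, ip] = ((cat == 0) | (cat == 2)).astype(np.int8)

    frame = pd.DataFrame(X, columns=names)
    return SurveyTable(frame, sites=site_of_survey)


# ---------------------------------------------------------------------------
# null-distribution study


@dataclass
class NullSimConfig:
    """Design of a null (no real associations) simulation study."""

    n_surveys: int = 795
    prevalences: dict[str, float] | pd.Series = field(default_factory=dict)
    n_sites: int | None = None
    sigma_site: float = 0.0
    site_effect_correlation: float = 0.0
    n_replicates: int = 200
    seed: int = 0
    significance_alpha: float = 0.05
    or_upper: float = 3.0
    or_lower: float = 1.0 / 3.0
    estimator: str = "raw"

    @classmethod
    def from_yaml(cls, path) -> "NullSimConfig":
        """Load a scenario from a YAML file with keys mirroring the fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class NullSimResult:
    """Per-replicate spurious-association counts under independence."""

    counts: pd.DataFrame
    config: NullSimConfig

    def summary(self) -> pd.DataFrame:
        """Median and spread of each spurious count across replicates."""
        q = self.counts.quantile([0.025, 0.25, 0.5, 0.75, 0.975])
        q.index.name = "quantile"
        return q

    def to_csv(self, counts_path, summary_path=None) -> None:
        self.counts.to_csv(counts_path, index_label="replicate")
        if summary_path is not None:
            self.summary().to_csv(summary_path)


def simulate_null(config: NullSimConfig) -> NullSimResult:
    """Spurious-association counts when every species is independent.

    Per replicate: draw independent presence for each species at its
    prevalence (modulated by site intercepts when ``sigma_site`` > 0),
    estimate every directed odds ratio, and count how many pass the
    indication / contraindication thresholds, overall and with an
    unadjusted Wald p-value below ``significance_alpha``. Zero and
    infinite odds ratios have no p-value and can only appear in the
    threshold-only tallies. Fully reproducible from the seed.
    """
    prev = pd.Series(config.prevalences, dtype=float)
    if len(prev) < 2:
        raise ValueError("need at least two species")
    if not ((prev > 0) & (prev < 1)).all():
        raise ValueError("prevalences must be strictly inside (0, 1)")
    if config.sigma_site > 0 and not config.n_sites:
        raise ValueError("site effects need n_sites")

    names = list(prev.index)
    n = config.n_surveys
    if config.n_sites:
        # distribute surveys over sites as evenly as possible
        per = np.full(config.n_sites, n // config.n_sites)
        per[: n % config.n_sites] += 1
        site_of_survey = np.repeat(np.arange(config.n_sites), per)
    else:
        site_of_survey = np.arange(n)

    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    base_logit = logit(prev.to_numpy())
    for child in children:
        rng = np.random.default_rng(child)
        if config.sigma_site > 0:
            u = _site_intercepts(
                rng,
                int(site_of_survey.max()) + 1,
                len(names),
                config.sigma_site,
                config.site_effect_correlation,
            )
            p = expit(base_logit[None, :] + u)[site_of_survey, :]
        else:
            p = expit(base_logit)[None, :]
        X = (rng.random((n, len(names))) < p).astype(np.int8)
        table = SurveyTable(pd.DataFrame(X, columns=names), sites=site_of_survey)
        estimates = estimate_all_pairs(table, estimator=config.estimator)
        ind = ind_sig = con = con_sig = 0
        for e in estimates:
            if math.isnan(e.or_value):
                continue
            sig = (not math.isnan(e.p_value)) and e.p_value < config.significance_alpha
            if e.or_value > config.or_upper:
                ind += 1
                ind_sig += sig
            elif e.or_value < config.or_lower:
                con += 1
                con_sig += sig
        rows.append(
            {
                "indications": ind,
                "indications_significant": ind_sig,
                "contraindications": con,
                "contraindications_significant": con_sig,
            }
        )
    return NullSimResult(counts=pd.DataFrame(rows), config=config)
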