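"""Declarative path-diagram specification for the MIMIC generalized SEM.

A :class:`ModelSpec` names the latent traits, their binary indicators (with
link functions and anchor loadings), the measured covariates, the structural
paths among latents, and the covariate->latent regressions. Identification
follows the anchor-loading convention: the first indicator declared for each
latent has its loading fixed at 1, the latent intercept is fixed at 0, and
the latent disturbance variance is a free parameter. Covariates are treated
as error-free causes and enter through treatment (dummy) coding against a
declared reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import yaml

LINK_NAMES = ("logit", "probit", "cloglog")


@dataclass(frozen=True)
class LinkFunction:
    """One of the three Bernoulli link functions: logit, probit, cloglog."""

    name: str = "logit"

    def __post_init__(self) -> None:
        if self.name not in LINK_NAMES:
            raise ValueError(f"unknown link {self.name!r}; expected one of {LINK_NAMES}")


@dataclass(frozen=True)
class LatentVariable:
    """A latent endogenous trait (its disturbance variance is a free parameter)."""

    name: str


@dataclass(frozen=True)
class Indicator:
    """A binary indicator loading on one latent trait.

    ``fixed_loading`` is None for a freely estimated loading; the anchor
    indicator of each latent carries ``fixed_loading=1.0``. ``direct_covariates``
    lists covariates whose dummy columns enter this indicator's linear
    predictor directly (bypassing the latents).
    """

    name: str
    latent: str
    link: str = "logit"
    fixed_loading: Optional[float] = None
    direct_covariates: tuple = ()


@dataclass(frozen=True)
class Covariate:
    """A measured categorical/binary cause with treatment coding.

    Dummy expansion produces one design column per non-reference level,
    named ``"<name>=<level>"``.
    """

    name: str
    levels: tuple
    reference: str

    @property
    def kind(self) -> str:
        return "binary" if len(self.levels) == 2 else "categorical"

    def design_levels(self) -> tuple:
        return tuple(l for l in self.levels if l != self.reference)

    def design_columns(self) -> tuple:
        return tuple(f"{self.name}={l}" for l in self.design_levels())


@dataclass(frozen=True)
class ModelSpec:
    latents: tuple
    indicators: tuple
    covariates: tuple
    latent_paths: tuple  # (from_latent, to_latent)
    covariate_to_latent_paths: tuple  # (covariate, latent)
    full_covariance: bool = False  # free off-diagonal latent disturbance Cholesky terms

    def __post_init__(self) -> None:
        object.__setattr__(self, "latents", tuple(self.latents))
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "latent_paths", tuple(tuple(p) for p in self.latent_paths))
        object.__setattr__(
            self, "covariate_to_latent_paths",
            tuple(tuple(p) for p in self.covariate_to_latent_paths),
        )

    # -- lookups ---------------------------------------------------------
    def latent_names(self) -> tuple:
        return tuple(l.name for l in self.latents)

    def indicator_names(self) -> tuple:
        return tuple(i.name for i in self.indicators)

    def covariate(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(f"covariate {name!r} not declared")

    def covariates_into(self, latent: str) -> tuple:
        """Covariates with a path into ``latent``, in declaration order."""
        order = {c.name: i for i, c in enumerate(self.covariates)}
        names = sorted(
            {c for (c, l) in self.covariate_to_latent_paths if l == latent},
            key=lambda n: order.get(n, len(order)),
        )
        return tuple(names)

    def with_link(self, link: str) -> "ModelSpec":
        """Copy of the spec with every indicator set to ``link``."""
        LinkFunction(link)
        return replace(
            self, indicators=tuple(replace(i, link=link) for i in self.indicators)
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "latents": [l.name for l in self.latents],
            "indicators": [
                {
                    "name": i.name,
                    "latent": i.latent,
                    "link": i.link,
                    "fixed_loading": i.fixed_loading,
                    "direct_covariates": list(i.direct_covariates),
                }
                for i in self.indicators
            ],
            "covariates": [
                {"name": c.name, "levels": list(c.levels), "reference": c.reference}
                for c in self.covariates
            ],
            "latent_paths": [list(p) for p in self.latent_paths],
            "covariate_to_latent_paths": [list(p) for p in self.covariate_to_latent_paths],
            "full_covariance": self.full_covariance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            latents=tuple(LatentVariable(n) for n in d["latents"]),
            indicators=tuple(
                Indicator(
                    name=i["name"],
                    latent=i["latent"],
                    link=i.get("link", "logit"),
                    fixed_loading=i.get("fixed_loading"),
                    direct_covariates=tuple(i.get("direct_covariates", ())),
                )
                for i in d["indicators"]
            ),
            covariates=tuple(
                Covariate(c["name"], tuple(c["levels"]), c["reference"])
                for c in d["covariates"]
            ),
            latent_paths=tuple(tuple(p) for p in d.get("latent_paths", ())),
            covariate_to_latent_paths=tuple(
                tuple(p) for p in d.get("covariate_to_latent_paths", ())
            ),
            full_covariance=bool(d.get("full_covariance", False)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    problems: list = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.problems.append(msg)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok

    def __iter__(self):
        return iter(self.problems)


def _latent_cycles(spec: ModelSpec) -> bool:
    """True if the latent->latent graph has a directed cycle (iterative DFS)."""
    adj: dict = {l.name: [] for l in spec.latents}
    for frm, to in spec.latent_paths:
        if frm in adj:
            adj[frm].append(to)
    color: dict = {n: 0 for n in adj}
    for start in adj:
        if color[start]:
            continue
        stack = [(start, iter(adj[start]))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in color:
                    continue
                if color[nxt] == 1:
                    return True
                if color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
    return False


def validate_spec(spec: ModelSpec) -> ValidationReport:
    """Check every structural invariant of the path diagram.

    Violations are collected into the report, never raised; an empty report
    means the spec is well-formed.
    """
    rep = ValidationReport()
    lat = set(spec.latent_names())
    cov = {c.name for c in spec.covariates}

    if len(lat) != len(spec.latents):
        rep.add("duplicate latent names")
    ind_names = spec.indicator_names()
    if len(set(ind_names)) != len(ind_names):
        rep.add("duplicate indicator names")
    if len(cov) != len(spec.covariates):
        rep.add("duplicate covariate names")

    for c in spec.covariates:
        if len(set(c.levels)) != len(c.levels):
            rep.add(f"covariate {c.name!r} has duplicate levels")
        if c.reference not in c.levels:
            rep.add(f"covariate {c.name!r}: reference level {c.reference!r} not in levels")
        if len(c.levels) < 2:
            rep.add(f"covariate {c.name!r} needs at least two levels")

    for i in spec.indicators:
        if i.latent not in lat:
            rep.add(f"indicator {i.name!r} loads on undeclared latent {i.latent!r}")
        try:
            LinkFunction(i.link)
        except ValueError:
            rep.add(f"indicator {i.name!r} has unknown link {i.link!r}")
        for d in i.direct_covariates:
            if d not in cov:
                rep.add(f"indicator {i.name!r} names undeclared direct covariate {d!r}")

    for frm, to in spec.latent_paths:
        if frm not in lat or to not in lat:
            rep.add(f"latent path ({frm!r} -> {to!r}) names an undeclared latent")
    for c, l in spec.covariate_to_latent_paths:
        if c not in cov:
            rep.add(f"covariate path ({c!r} -> {l!r}) names an undeclared covariate")
        if l not in lat:
            rep.add(f"covariate path ({c!r} -> {l!r}) names an undeclared latent")

    if _latent_cycles(spec):
        rep.add("latent dependency graph contains a cycle")

    # anchoring: exactly one fixed-to-1 loading per latent
    for l in spec.latents:
        mine = [i for i in spec.indicators if i.latent == l.name]
        anchors = [i for i in mine if i.fixed_loading == 1.0]
        if not mine or not anchors:
            rep.add(f"unanchored latent {l.name!r} (needs an indicator with loading fixed at 1)")
        elif len(anchors) > 1:
            rep.add(f"latent {l.name!r} has multiple anchor indicators")

    return rep


STRUCTURAL_MARKERS = ("undeclared", "cycle", "duplicate", "unknown link", "reference level")


def structural_problems(report: ValidationReport) -> list:
    """Violations that make the spec unusable (vs. identification warnings)."""
    return [p for p in report.problems if any(m in p for m in STRUCTURAL_MARKERS)]


# ---------------------------------------------------------------------------
# parameter layout


@dataclass(frozen=True)
class ParameterLayout:
    """Canonical bijection between free parameters and a flat vector.

    Block order: indicator intercepts, free loadings, direct covariate
    coefficients, covariate->latent regressions, latent->latent structural
    coefficients, log disturbance SDs (plus free off-diagonal Cholesky terms
    when the spec allows a full disturbance covariance). Path blocks are
    sorted canonically so the layout does not depend on declaration order.
    """

    names: tuple

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names


def param_layout(spec: ModelSpec) -> ParameterLayout:
    """Build the canonical parameter layout; raises on structurally invalid specs."""
    rep = validate_spec(spec)
    bad = structural_problems(rep)
    if bad:
        raise ValueError("invalid model spec: " + "; ".join(bad))

    names: list = []
    for i in spec.indicators:
        names.append(f"intercept:{i.name}")
    for i in spec.indicators:
        if i.fixed_loading is None:
            names.append(f"loading:{i.name}")
    for i in spec.indicators:
        for covname in i.direct_covariates:
            for col in spec.covariate(covname).design_columns():
                names.append(f"direct:{i.name}:{col}")
    for l in spec.latents:
        for covname in spec.covariates_into(l.name):
            for col in spec.covariate(covname).design_columns():
                names.append(f"reg:{l.name}<-{col}")
    lat_index = {n: k for k, n in enumerate(spec.latent_names())}
    for frm, to in sorted(set(spec.latent_paths), key=lambda p: (lat_index[p[1]], lat_index[p[0]])):
        names.append(f"struct:{to}<-{frm}")
    for l in spec.latents:
        names.append(f"lnsd:{l.name}")
    if spec.full_covariance:
        lnames = spec.latent_names()
        for row in range(1, len(lnames)):
            for col in range(row):
                names.append(f"lchol:{lnames[row]}:{lnames[col]}")
    return ParameterLayout(names=tuple(names))


# ---------------------------------------------------------------------------
# the default study model


def default_paper_spec(direct_on: str = "all") -> ModelSpec:
    """The study model: malnutrition and morbidity MIMIC diagram.

    Latent malnutrition is measured by stunting (anchor), wasting and
    underweight; latent morbidity by diarrhea (anchor), cough and fever; one
    structural path malnutrition -> morbidity. Child sex and child age group
    enter the indicators directly. ``direct_on`` may be ``"all"`` (default:
    all six indicators) or ``"five"`` (all but cough, the narrower reading
    of which indicators take the direct child-level effects).
    """
    covs = (
        Covariate("mother_bmi", ("<18.5", ">=18.5"), "<18.5"),
        Covariate("birth_order", ("1st", "2nd-3rd", "4th+"), "1st"),
        Covariate("birth_interval", ("<24", "24-47", "48+"), "<24"),
        Covariate("wealth_index", ("poor", "middle", "rich"), "poor"),
        Covariate("mother_education", ("none", "primary", "secondary+"), "none"),
        Covariate("husband_education", ("none", "primary", "secondary", "higher"), "none"),
        Covariate("water_source", ("piped", "public_tap", "protected_spring", "other"), "piped"),
        Covariate("toilet_facility", ("none", "latrine", "flush"), "none"),
        Covariate("breastfeeding", ("no", "yes"), "no"),
        Covariate("anemia", ("anemic", "not_anemic"), "anemic"),
        Covariate("mother_work", ("no", "yes"), "no"),
        Covariate("place_of_delivery", ("home", "health_center"), "home"),
        Covariate("child_sex", ("male", "female"), "male"),
        Covariate("child_age_group", ("0-11", "12-23", "24-59"), "0-11"),
    )
    direct = ("child_sex", "child_age_group")

    def _ind(name: str, latent: str, anchor: bool) -> Indicator:
        takes_direct = direct_on == "all" or name != "cough"
        return Indicator(
            name=name,
            latent=latent,
            link="logit",
            fixed_loading=1.0 if anchor else None,
            direct_covariates=direct if takes_direct else (),
        )

    indicators = (
        _ind("stunting", "malnutrition", True),
        _ind("wasting", "malnutrition", False),
        _ind("underweight", "malnutrition", False),
        _ind("diarrhea", "morbidity", True),
        _ind("cough", "morbidity", False),
        _ind("fever", "morbidity", False),
    )
    into_malnutrition = (
        "mother_bmi", "birth_interval", "wealth_index", "mother_education",
        "breastfeeding", "anemia", "mother_work", "place_of_delivery",
    )
    into_morbidity = (
        "mother_bmi", "birth_order", "birth_interval", "water_source",
        "toilet_facility", "breastfeeding", "anemia", "mother_work",
        "place_of_delivery", "husband_education",
    )
    return ModelSpec(
        latents=(LatentVariable("malnutrition"), LatentVariable("morbidity")),
        indicators=indicators,
        covariates=covs,
        latent_paths=(("malnutrition", "morbidity"),),
        covariate_to_latent_paths=tuple((c, "malnutrition") for c in into_malnutrition)
        + tuple((c, "morbidity") for c in into_morbidity),
    )
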