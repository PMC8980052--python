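"""Synthetic matched-cohort generator with planted ground truth.

Generates 1:1 matched case/reference cohorts of hospital visits carrying
ICD-10-like 3-4 character diagnosis codes.  Latent "planted factors" make
groups of codes co-occur: a patient is a *carrier* of a factor with a
role-dependent probability (reference prevalence, multiplied through an
odds ratio for cases), and carriers emit each member code at each visit of
the matching phase with a fixed emission probability.  Background codes are
emitted independently at every visit.

Transition structure between pre-injury factors and event-phase targets
(event factors, injury-severity categories or external-cause indicators) is
planted through a Gaussian threshold copula: carrier indicators are
thresholded latent standard normals, and a planted link with strength
``rho`` sets the latent correlation between the two dimensions to ``rho``.
The implied phi (Pearson on binaries) correlation is computed numerically
from the bivariate normal rectangle probability; see :func:`target_phi`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantedFactor",
    "TransitionLink",
    "SimulationConfig",
    "GroundTruth",
    "default_code_universe",
    "generate_cohort",
    "plant_transition",
    "sample_carriers",
    "target_phi",
    "TBI_CODES",
    "SEVERITY_CODE",
    "CAUSE_CODE",
]

#: Diagnosis codes (dotless) that define the index event; matched by prefix.
TBI_CODES = ("S020", "S021", "S023", "S027", "S028", "S029", "S040", "S071", "S06")

#: Code emitted at the injury visit for each severity designation.
SEVERITY_CODE = {
    "unspecified": "S060",
    "mild": "S061",
    "moderate": "S062",
    "severe": "S065",
}

#: External-cause code emitted at the injury visit for each cause indicator.
CAUSE_CODE = {
    "falls": "W19",
    "struck": "W22",
    "MVC": "V43",
    "sports": "W21",
    "assault": "X99",
    "other": "Y30",
}

# Marginal rates used when a label is not targeted by a planted link.
_SEVERITY_BASE = {"unspecified": 0.43, "mild": 0.35, "moderate": 0.04, "severe": 0.18}
_CAUSE_BASE = {
    "falls": 0.45,
    "struck": 0.36,
    "MVC": 0.10,
    "sports": 0.25,
    "assault": 0.07,
    "other": 0.12,
}

_AGE_BANDS = ("0-17", "18-34", "35-49", "50-64", "65-79", "80+")
_AGE_WEIGHTS = (0.22, 0.24, 0.18, 0.16, 0.13, 0.07)

# Chapter letters that cannot collide with injury (S), external-cause
# (V/W/X/Y) or provisional (U) codes.
_UNIVERSE_LETTERS = "ABCDEFGHIJKLMNR"


def default_code_universe(n_codes: int) -> list[str]:
    """First ``n_codes`` three-character codes from non-injury ICD chapters."""
    if n_codes < 1:
        raise ValueError("n_codes must be positive")
    out = []
    for letter in _UNIVERSE_LETTERS:
        for i in range(100):
            out.append(f"{letter}{i:02d}")
            if len(out) == n_codes:
                return out
    raise ValueError(f"n_codes={n_codes} exceeds available universe ({len(out)})")


@dataclass(frozen=True)
class PlantedFactor:
    """A latent comorbidity factor planted into the generator."""

    factor_id: str
    phase: str  # "pre_injury" | "event"
    member_codes: tuple[str, ...]
    carrier_prevalence_reference: float
    odds_ratio_case: float
    emission_probability: float

    def __post_init__(self):
        if self.phase not in ("pre_injury", "event"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.member_codes:
            raise ValueError(f"factor {self.factor_id}: empty member code set")
        if not 0.0 < self.carrier_prevalence_reference < 1.0:
            raise ValueError(f"factor {self.factor_id}: prevalence outside (0,1)")
        if self.odds_ratio_case <= 0:
            raise ValueError(f"factor {self.factor_id}: odds ratio must be > 0")
        if not 0.0 <= self.emission_probability <= 1.0:
            raise ValueError(f"factor {self.factor_id}: emission prob outside [0,1]")

    @property
    def carrier_prevalence_case(self) -> float:
        """Case carrier prevalence implied by the planted odds ratio."""
        p = self.carrier_prevalence_reference
        odds = self.odds_ratio_case * p / (1.0 - p)
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class TransitionLink:
    """Planted latent correlation between a pre-injury factor and an event target.

    ``event_target_id`` is an event-phase factor id, ``"severity:<cat>"`` or
    ``"cause:<cat>"``.
    """

    pre_factor_id: str
    event_target_id: str
    rho: float

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic matched cohort.

    Defaults give a desk-scale cohort: 2,000 matched pairs over a 200-code
    universe, visits spread over a decade-long study window.
    """

    n_pairs: int = 2000
    code_universe: list[str] = field(default_factory=lambda: default_code_universe(200))
    planted_factors: list[PlantedFactor] = field(default_factory=list)
    background_code_prevalence: float = 0.02
    study_start: str = "2007-04-01"
    study_end: str = "2016-03-31"
    visits_mean: float = 8.0
    visits_dispersion: float = 2.0
    severity_base: dict[str, float] = field(default_factory=lambda: dict(_SEVERITY_BASE))
    cause_base: dict[str, float] = field(default_factory=lambda: dict(_CAUSE_BASE))
    transition_links: list[TransitionLink] = field(default_factory=list)
    seed: int = 0

    @property
    def n_codes(self) -> int:
        return len(self.code_universe)

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if not self.code_universe:
            raise ValueError("empty code universe")
        if not 0.0 <= self.background_code_prevalence <= 1.0:
            raise ValueError("background_code_prevalence outside [0,1]")
        if self.visits_mean < 1.0:
            raise ValueError("degenerate visit distribution: mean below one visit")
        if self.visits_dispersion <= 0:
            raise ValueError("visits_dispersion must be positive")
        universe = set(self.code_universe)
        ids = [f.factor_id for f in self.planted_factors]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate factor ids")
        for f in self.planted_factors:
            missing = set(f.member_codes) - universe
            if missing:
                raise ValueError(
                    f"factor {f.factor_id}: member codes not in universe: {sorted(missing)}"
                )
        by_id = {f.factor_id: f for f in self.planted_factors}
        for link in self.transition_links:
            pre = by_id.get(link.pre_factor_id)
            if pre is None or pre.phase != "pre_injury":
                raise ValueError(f"link references unknown pre-injury factor {link.pre_factor_id!r}")
            _validate_event_target(link.event_target_id, by_id, self)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _validate_event_target(target: str, by_id: dict, config: SimulationConfig) -> None:
    if target.startswith("severity:"):
        cat = target.split(":", 1)[1]
        if cat not in config.severity_base:
            raise ValueError(f"unknown severity category {cat!r}")
    elif target.startswith("cause:"):
        cat = target.split(":", 1)[1]
        if cat not in config.cause_base:
            raise ValueError(f"unknown cause category {cat!r}")
    else:
        fac = by_id.get(target)
        if fac is None or fac.phase != "event":
            raise ValueError(f"link references unknown event target {target!r}")


def plant_transition(
    config: SimulationConfig, pre_factor_id: str, event_target_id: str, rho: float
) -> SimulationConfig:
    """Return a copy of ``config`` with one more planted transition link."""
    link = TransitionLink(pre_factor_id, event_target_id, rho)
    new = dataclasses.replace(
        config, transition_links=list(config.transition_links) + [link]
    )
    new.validate()
    return new


def target_phi(rho: float, p_a: float, p_b: float) -> float:
    """Phi correlation implied by a Gaussian threshold copula.

    Two binaries are generated by thresholding standard normals with latent
    correlation ``rho`` at marginal rates ``p_a`` and ``p_b``.  The joint
    rate is the bivariate normal rectangle probability
    ``p11 = P(Z_a < q_a, Z_b < q_b)``, and
    ``phi = (p11 - p_a p_b) / sqrt(p_a (1-p_a) p_b (1-p_b))``.
    """
    qa, qb = stats.norm.ppf(p_a), stats.norm.ppf(p_b)
    p11 = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([qa, qb])
    return float((p11 - p_a * p_b) / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b)))


@dataclass
class GroundTruth:
    """Everything planted, for validating downstream recovery."""

    patient_ids: list[str]
    roles: np.ndarray  # "case"/"reference" per patient
    carriers: pd.DataFrame  # patients x factor_id binary indicators
    factor_odds_ratios: dict[str, float]
    code_marginal_odds_ratios: dict[str, float]
    severity: pd.DataFrame  # case patient_id -> severity category
    causes: pd.DataFrame  # case patient_id x cause indicator
    transition_links: list[TransitionLink]
    transition_target_phi: dict[tuple[str, str], float]

    def to_json(self, path) -> None:
        payload = {
            "factor_odds_ratios": self.factor_odds_ratios,
            "code_marginal_odds_ratios": self.code_marginal_odds_ratios,
            "transition_links": [dataclasses.asdict(l) for l in self.transition_links],
            "transition_target_phi": {
                f"{a}->{b}": v for (a, b), v in self.transition_target_phi.items()
            },
            "carriers": {
                "patient_id": self.patient_ids,
                "role": self.roles.tolist(),
                **{c: self.carriers[c].astype(int).tolist() for c in self.carriers.columns},
            },
            "severity": self.severity["severity"].to_dict(),
            "causes": {c: self.causes[c].astype(int).to_dict() for c in self.causes.columns},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# carrier / label sampling


def _latent_dimensions(config: SimulationConfig):
    """Ordered latent dimensions: factors first, then linked label targets."""
    dims = [f.factor_id for f in config.planted_factors]
    for link in config.transition_links:
        if link.event_target_id not in dims:
            dims.append(link.event_target_id)
    return dims


def _latent_correlation(config: SimulationConfig, dims: list[str]) -> np.ndarray:
    idx = {d: i for i, d in enumerate(dims)}
    corr = np.eye(len(dims))
    for link in config.transition_links:
        i, j = idx[link.pre_factor_id], idx[link.event_target_id]
        corr[i, j] = corr[j, i] = link.rho
    return corr


def sample_carriers(
    config: SimulationConfig, rng: np.random.Generator, n_pairs: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw carrier indicators (and linked label indicators) for all patients.

    Returns a (2*n_pairs)-row DataFrame with one binary column per latent
    dimension, ordered case_0, ref_0, case_1, ref_1, ..., plus the role array.
    Thresholds are role specific (case prevalence follows from the planted
    odds ratio) while the latent correlation is shared, so planted links act
    within both roles.
    """
    n_pairs = config.n_pairs if n_pairs is None else n_pairs
    n = 2 * n_pairs
    roles = np.empty(n, dtype=object)
    roles[0::2] = "case"
    roles[1::2] = "reference"
    dims = _latent_dimensions(config)
    if not dims:
        return pd.DataFrame(index=range(n)), roles

    corr = _latent_correlation(config, dims)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("planted transition links give a non-PSD latent correlation") from exc
    z = rng.standard_normal((n, len(dims))) @ chol.T

    by_id = {f.factor_id: f for f in config.planted_factors}
    is_case = roles == "case"
    cols = {}
    for j, d in enumerate(dims):
        if d in by_id:
            f = by_id[d]
            thr = np.where(
                is_case,
                stats.norm.ppf(f.carrier_prevalence_case),
                stats.norm.ppf(f.carrier_prevalence_reference),
            )
        elif d.startswith("severity:"):
            thr = stats.norm.ppf(config.severity_base[d.split(":", 1)[1]])
        else:  # cause:<cat>
            thr = stats.norm.ppf(config.cause_base[d.split(":", 1)[1]])
        cols[d] = (z[:, j] < thr).astype(np.int8)
    return pd.DataFrame(cols), roles


def _sample_labels(
    config: SimulationConfig, carriers: pd.DataFrame, case_idx: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Severity category and cause indicators for each case.

    Linked categories use their copula indicator from ``carriers``; the
    remaining severity mass is renormalised over unlinked categories, and
    unlinked causes are independent Bernoulli draws.
    """
    n_cases = len(case_idx)
    sev_cats = list(config.severity_base)
    linked_sev = [c for c in sev_cats if f"severity:{c}" in carriers.columns]
    severity = np.empty(n_cases, dtype=object)
    assigned = np.zeros(n_cases, dtype=bool)
    for cat in linked_sev:
        ind = carriers[f"severity:{cat}"].to_numpy()[case_idx].astype(bool)
        take = ind & ~assigned
        severity[take] = cat
        assigned |= take
    rest = [c for c in sev_cats if c not in linked_sev]
    if rest:
        w = np.array([config.severity_base[c] for c in rest], dtype=float)
        w /= w.sum()
        draw = rng.choice(len(rest), size=n_cases, p=w)
        severity[~assigned] = np.array(rest, dtype=object)[draw[~assigned]]
    elif not assigned.all():
        severity[~assigned] = "unspecified"

    causes = {}
    for cat, base in config.cause_base.items():
        key = f"cause:{cat}"
        if key in carriers.columns:
            causes[cat] = carriers[key].to_numpy()[case_idx].astype(np.int8)
        else:
            causes[cat] = (rng.random(n_cases) < base).astype(np.int8)
    return severity, pd.DataFrame(causes)


# ---------------------------------------------------------------------------
# visit stream generation


def _visit_layout(n_visits: np.ndarray):
    """Before/after split so the rank midpoint visit is the pseudo-index.

    With ``n = 2k+1`` visits the middle rank is ``k+1``; with ``n = 2k`` the
    earlier of the two middle visits has rank ``k``.  Putting ``after = n//2``
    visits strictly after the pseudo-index pins the midpoint to it exactly.
    """
    after = n_visits // 2
    before = n_visits - 1 - after
    return before, after


def _code_odds_ratio(config: SimulationConfig, factor: PlantedFactor) -> float:
    """Approximate per-code marginal OR at one event-window visit."""
    bg = config.background_code_prevalence
    em = factor.emission_probability

    def prev(p_carrier):
        return 1.0 - (1.0 - bg) * (1.0 - p_carrier * em)

    p_ref = prev(factor.carrier_prevalence_reference)
    p_case = prev(factor.carrier_prevalence_case)
    return (p_case / (1 - p_case)) / (p_ref / (1 - p_ref))


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long-format visit table and its ground truth.

    Each pair shares matching covariates exactly.  Cases carry a single
    injury visit (first TBI-coded visit, defining the index date) bearing a
    severity-specific S06.x code and one external-cause code per active
    cause indicator.  References have no TBI-coded visit; their visit layout
    pins the rank-midpoint visit to the pseudo-index date so that planted
    event-phase structure is visible in the downstream event window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_pairs
    n_patients = 2 * n_pairs

    carriers, roles = sample_carriers(config, rng)
    is_case = roles == "case"
    case_idx = np.flatnonzero(is_case)
    severity, causes = _sample_labels(config, carriers, case_idx, rng)

    # pair-level matching covariates, shared exactly within pair
    sex = rng.choice(["M", "F"], size=n_pairs, p=[0.57, 0.43])
    age = rng.choice(_AGE_BANDS, size=n_pairs, p=_AGE_WEIGHTS)
    rural = rng.choice([0, 1], size=n_pairs, p=[0.84, 0.16])
    income = rng.integers(1, 6, size=n_pairs)

    # visit counts: 1 + negative binomial with mean visits_mean - 1
    r = config.visits_dispersion
    mu = config.visits_mean - 1.0
    n_visits = 1 + rng.negative_binomial(r, r / (r + mu), size=n_patients)

    start = np.datetime64(config.study_start)
    end = np.datetime64(config.study_end)
    lo = start + np.timedelta64(1826, "D")
    hi = end - np.timedelta64(31, "D")
    if hi <= lo:
        raise ValueError("study window too short for a 5-year pre-injury phase")
    index_dates = lo + rng.integers(0, (hi - lo).astype(int) + 1, size=n_patients).astype(
        "timedelta64[D]"
    )

    before, after = _visit_layout(n_visits)
    total_visits = int(n_visits.sum())
    visit_patient = np.repeat(np.arange(n_patients), n_visits)

    # per-visit day offsets from the patient's (pseudo-)index date
    offsets = np.empty(total_visits, dtype=np.int64)
    pos = 0
    neg_draw = rng.integers(1, 1826, size=int(before.sum()))
    pos_draw = rng.integers(1, 1826, size=int(after.sum()))
    bi = pi = 0
    for p in range(n_patients):
        nb, na = int(before[p]), int(after[p])
        offsets[pos : pos + nb] = -np.sort(neg_draw[bi : bi + nb])[::-1]
        offsets[pos + nb] = 0
        offsets[pos + nb + 1 : pos + nb + 1 + na] = np.sort(pos_draw[pi : pi + na])
        bi += nb
        pi += na
        pos += nb + 1 + na
    is_index_visit = offsets == 0
    visit_dates = index_dates[visit_patient] + offsets.astype("timedelta64[D]")

    # generator-side phase of each visit relative to the pseudo-index
    v_event = np.abs(offsets) <= 30
    v_pre = (offsets >= -1826) & (offsets <= -31)

    codes = np.array(config.code_universe)
    emitted_vi: list[np.ndarray] = []
    emitted_code: list[np.ndarray] = []

    bg = config.background_code_prevalence
    if bg > 0:
        # chunked to bound the boolean matrix size
        chunk = max(1, int(2_000_000 // max(1, len(codes))))
        for s in range(0, total_visits, chunk):
            e = min(s + chunk, total_visits)
            vi, ci = np.nonzero(rng.random((e - s, len(codes))) < bg)
            emitted_vi.append(vi + s)
            emitted_code.append(codes[ci])

    for f in config.planted_factors:
        carr = carriers[f.factor_id].to_numpy().astype(bool)
        phase_mask = v_event if f.phase == "event" else v_pre
        vmask = phase_mask & carr[visit_patient]
        vis = np.flatnonzero(vmask)
        if len(vis) == 0:
            continue
        member = np.array(f.member_codes)
        vi, ci = np.nonzero(rng.random((len(vis), len(member))) < f.emission_probability)
        emitted_vi.append(vis[vi])
        emitted_code.append(member[ci])

    # injury visit codes for cases: severity S06.x + active cause codes
    case_index_visit = np.flatnonzero(is_index_visit & is_case[visit_patient])
    case_of_visit = {int(visit_patient[v]): v for v in case_index_visit}
    inj_vi, inj_code = [], []
    for row, p in enumerate(case_idx):
        v = case_of_visit[int(p)]
        inj_vi.append(v)
        inj_code.append(SEVERITY_CODE[severity[row]])
        for cat in causes.columns:
            if causes.iloc[row][cat]:
                inj_vi.append(v)
                inj_code.append(CAUSE_CODE[cat])
    if inj_vi:
        emitted_vi.append(np.asarray(inj_vi))
        emitted_code.append(np.asarray(inj_code, dtype=object))

    all_vi = np.concatenate(emitted_vi) if emitted_vi else np.empty(0, dtype=int)
    all_code = np.concatenate(emitted_code) if emitted_code else np.empty(0, dtype=object)
    code_series = (
        pd.Series(all_code.astype(str), index=all_vi)
        .groupby(level=0)
        .agg(lambda s: ";".join(sorted(set(s))))
    )
    visit_codes = np.full(total_visits, "", dtype=object)
    visit_codes[code_series.index.to_numpy()] = code_series.to_numpy()

    pair_of_patient = np.repeat(np.arange(n_pairs), 2)
    patient_ids = np.array([f"P{i:06d}" for i in range(n_patients)])
    table = pd.DataFrame(
        {
            "patient_id": patient_ids[visit_patient],
            "pair_id": np.array([f"M{i:06d}" for i in pair_of_patient])[visit_patient],
            "role": roles[visit_patient],
            "sex": sex[pair_of_patient][visit_patient],
            "age_band": age[pair_of_patient][visit_patient],
            "rural": rural[pair_of_patient][visit_patient],
            "income_q": income[pair_of_patient][visit_patient],
            "visit_date": pd.to_datetime(visit_dates),
            "setting": rng.choice(["ED", "acute"], size=total_visits, p=[0.85, 0.15]),
            "codes": visit_codes,
        }
    )

    by_id = {f.factor_id: f for f in config.planted_factors}
    code_or = {}
    for f in config.planted_factors:
        if f.phase == "event":
            for c in f.member_codes:
                code_or[c] = _code_odds_ratio(config, f)
    phi = {}
    for link in config.transition_links:
        pre = by_id[link.pre_factor_id]
        tgt = link.event_target_id
        if tgt in by_id:
            p_b = by_id[tgt].carrier_prevalence_case
        elif tgt.startswith("severity:"):
            p_b = config.severity_base[tgt.split(":", 1)[1]]
        else:
            p_b = config.cause_base[tgt.split(":", 1)[1]]
        phi[(link.pre_factor_id, tgt)] = target_phi(
            link.rho, pre.carrier_prevalence_case, p_b
        )

    truth = GroundTruth(
        patient_ids=list(patient_ids),
        roles=roles,
        carriers=carriers,
        factor_odds_ratios={f.factor_id: f.odds_ratio_case for f in config.planted_factors},
        code_marginal_odds_ratios=code_or,
        severity=pd.DataFrame({"severity": severity}, index=patient_ids[case_idx]),
        causes=causes.set_axis(patient_ids[case_idx], axis=0),
        transition_links=list(config.transition_links),
        transition_target_phi=phi,
    )
    return table, truth
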