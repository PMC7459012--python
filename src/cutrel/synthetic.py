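"""Synthetic exam generator.

Emulates a sample of high-stakes medical end-of-term exams mixing
single-best-answer (Type A, scored 0/1) and multiple true-false (MTF,
scored 0/0.5/1) items.  Responses are simulated from the same 1-PL
partial credit model that the analysis side estimates, so parameter
recovery is well defined.  Cohorts are standard-normal abilities with
optional symmetric truncation; a year-linked truncation schedule
reproduces the progressive homogenisation of medical cohorts (weaker
students drop out, so later study years span a narrower ability range).

Default bands follow the study conditions this package is designed
around: 32 exams, 146-378 examinees, 59-150 items, roughly 19-53% MTF
items (mean ~31%), content-based cut scores between 47.5% and 70% of the
maximum points (mean 56.6%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._pcm import category_probs

TYPE_A = "typeA"
MTF = "mtf"

#: points carried by one category step, per item kind
POINT_WEIGHTS = {TYPE_A: 1.0, MTF: 0.5}
#: allowed point values per item kind
ALLOWED_SCORES = {TYPE_A: (0.0, 1.0), MTF: (0.0, 0.5, 1.0)}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class ItemSpec:
    """One exam item: its kind, option count and PCM step parameters."""

    item_id: str
    kind: str
    n_options: int
    step_params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in (TYPE_A, MTF):
            raise ConfigError(f"unknown item kind {self.kind!r}")
        expected_steps = 1 if self.kind == TYPE_A else 2
        if len(self.step_params) != expected_steps:
            raise ConfigError(
                f"{self.item_id}: {self.kind} items need {expected_steps} "
                f"step parameter(s), got {len(self.step_params)}"
            )
        expected_options = 5 if self.kind == TYPE_A else 4
        if self.n_options != expected_options:
            raise ConfigError(
                f"{self.item_id}: {self.kind} items have {expected_options} options"
            )
        if not all(np.isfinite(self.step_params)):
            raise ConfigError(f"{self.item_id}: non-finite step parameters")

    @property
    def n_categories(self) -> int:
        return len(self.step_params) + 1

    @property
    def point_weight(self) -> float:
        """Points per category step (1 for Type A, 0.5 for MTF)."""
        return POINT_WEIGHTS[self.kind]


@dataclass(frozen=True)
class ExamSpec:
    """An exam: items, cut score (percent of maximum points), school, year."""

    exam_id: str
    items: tuple[ItemSpec, ...]
    cut_percent: float
    school: str = "A"
    year_of_study: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.cut_percent < 100:
            raise ConfigError(f"cut_percent must lie in (0, 100), got {self.cut_percent}")
        if not 1 <= self.year_of_study <= 5:
            raise ConfigError(f"year_of_study must lie in 1..5, got {self.year_of_study}")
        if not self.items:
            raise ConfigError("exam has no items")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_points(self) -> float:
        # each item is worth one point regardless of kind
        return float(len(self.items))

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def item_kinds(self) -> list[str]:
        return [it.kind for it in self.items]

    @property
    def pct_mtf(self) -> float:
        return 100.0 * sum(it.kind == MTF for it in self.items) / len(self.items)

    def drop_items(self, item_ids: Sequence[str]) -> "ExamSpec":
        """Spec with the given items removed (post-hoc eliminated items)."""
        drop = set(item_ids)
        unknown = drop - set(self.item_ids)
        if unknown:
            raise KeyError(f"unknown item ids: {sorted(unknown)}")
        kept = tuple(it for it in self.items if it.item_id not in drop)
        return replace(self, items=kept)


@dataclass(frozen=True)
class CohortSpec:
    """Examinee cohort: ability distribution and optional range restriction."""

    n_examinees: int
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    truncation_low: float | None = None
    truncation_high: float | None = None

    def __post_init__(self) -> None:
        if self.n_examinees < 2:
            raise ConfigError("cohort needs at least 2 examinees")
        if self.ability_sd <= 0:
            raise ConfigError("ability_sd must be positive")
        if (
            self.truncation_low is not None
            and self.truncation_high is not None
            and not self.truncation_low < self.truncation_high
        ):
            raise ConfigError("truncation_low must be below truncation_high")


@dataclass
class ResponseMatrix:
    """Scored examinee-by-item table (points: 0/1 for Type A, 0/0.5/1 for MTF)."""

    scores: pd.DataFrame  # index: examinee ids, columns: item ids
    item_kinds: list[str]

    def __post_init__(self) -> None:
        if len(self.item_kinds) != self.scores.shape[1]:
            raise ValueError("item_kinds length must match number of columns")

    @property
    def n_examinees(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def examinee_ids(self) -> list:
        return list(self.scores.index)

    @property
    def item_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def max_points(self) -> float:
        return float(self.scores.shape[1])

    def validate(self) -> None:
        """Raise ValueError naming the offending cell on any illegal entry."""
        values = self.scores.to_numpy(dtype=float)
        if np.isnan(values).any():
            v, i = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing entry at examinee {self.scores.index[v]!r}, "
                f"item {self.scores.columns[i]!r}"
            )
        for j, kind in enumerate(self.item_kinds):
            allowed = ALLOWED_SCORES[kind]
            bad = ~np.isin(values[:, j], allowed)
            if bad.any():
                v = int(np.argmax(bad))
                raise ValueError(
                    f"illegal score {values[v, j]} for {kind} item "
                    f"{self.scores.columns[j]!r} (examinee {self.scores.index[v]!r}); "
                    f"allowed: {allowed}"
                )
        if np.unique(values.sum(axis=1)).size < 2:
            raise ValueError(
                "all examinees share one total score; variance-based "
                "quantities are undefined"
            )

    def drop_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        drop = set(item_ids)
        keep = [c for c in self.scores.columns if c not in drop]
        kinds = [k for c, k in zip(self.scores.columns, self.item_kinds) if c not in drop]
        return ResponseMatrix(self.scores[keep], kinds)


# --------------------------------------------------------------------------
# scoring raw MTF ratings

def score_mtf_item(ratings_correct: int, n_ratings: int = 4) -> float:
    """Partial-credit score for one MTF item from its true/false ratings.

    Full point when every rating is marked correctly, half a point when
    more than half (but not all) are, zero otherwise.
    """
    if not 0 <= ratings_correct <= n_ratings:
        raise ValueError(
            f"ratings_correct={ratings_correct} outside [0, {n_ratings}]"
        )
    if ratings_correct == n_ratings:
        return 1.0
    if ratings_correct > n_ratings / 2:
        return 0.5
    return 0.0


# --------------------------------------------------------------------------
# generator configuration

def _as_band(value, name: str) -> tuple[float, float]:
    """Accept a scalar (degenerate band) or a (low, high) pair."""
    if np.isscalar(value):
        return float(value), float(value)
    lo, hi = value
    if hi < lo:
        raise ConfigError(f"{name}: empty band ({lo}, {hi})")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ExamGeneratorConfig:
    """Bands and distributions for a single generated exam.

    ``mtf_fraction`` and ``cut_percent`` are drawn from normals truncated
    to their band (centre/spread below); a scalar band pins the value.
    Item locations are normal on the logit scale; an MTF item's two step
    parameters straddle its location by a uniformly drawn spread, giving
    ordered thresholds and a usable middle (half-point) category.
    """

    n_items: tuple[int, int] | int = (59, 150)
    mtf_fraction: tuple[float, float] | float = (0.1897, 0.5333)
    mtf_fraction_mean: float = 0.306
    mtf_fraction_sd: float = 0.08
    cut_percent: tuple[float, float] | float = (47.5, 70.0)
    cut_percent_mean: float = 56.6
    cut_percent_sd: float = 4.7
    difficulty_mean: float = -1.0
    difficulty_sd: float = 1.3
    mtf_step_spread: tuple[float, float] | float = (0.5, 1.5)

    def __post_init__(self) -> None:
        lo, hi = _as_band(self.mtf_fraction, "mtf_fraction")
        if not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ConfigError("mtf_fraction band must lie in [0, 1]")
        k_lo, k_hi = _as_band(self.n_items, "n_items")
        if k_lo < 2:
            raise ConfigError("n_items must be at least 2")
        _as_band(self.cut_percent, "cut_percent")
        _as_band(self.mtf_step_spread, "mtf_step_spread")


@dataclass(frozen=True)
class StudyGeneratorConfig:
    """Bands for a whole multi-exam study.

    ``truncation_base``/``truncation_step`` define the year-linked range
    restriction: a cohort in study year y has abilities truncated to
    mean +/- (base - step*(y-1)) logits, so later years are tighter.
    Set ``year_truncation=False`` for unrestricted cohorts.
    """

    n_exams: int = 32
    exam: ExamGeneratorConfig = field(default_factory=ExamGeneratorConfig)
    n_examinees: tuple[int, int] | int = (146, 378)
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    year_truncation: bool = True
    truncation_base: float = 3.5
    truncation_step: float = 0.65
    schools: tuple[str, ...] = ("A", "B", "C")
    years: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise ConfigError("n_exams must be at least 1")
        _as_band(self.n_examinees, "n_examinees")

    def cohort_for_year(self, year: int, n_examinees: int) -> CohortSpec:
        low = high = None
        if self.year_truncation:
            half = self.truncation_base - self.truncation_step * (year - 1)
            if half <= 0:
                raise ConfigError("truncation schedule collapses to zero width")
            low = self.ability_mean - half * self.ability_sd
            high = self.ability_mean + half * self.ability_sd
        return CohortSpec(
            n_examinees=n_examinees,
            ability_mean=self.ability_mean,
            ability_sd=self.ability_sd,
            truncation_low=low,
            truncation_high=high,
        )


# --------------------------------------------------------------------------
# generation

def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, band: tuple[float, float]
) -> float:
    lo, hi = band
    if lo == hi:
        return lo
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_exam_spec(
    config: ExamGeneratorConfig,
    seed: int | np.random.SeedSequence,
    exam_id: str = "exam",
    school: str = "A",
    year_of_study: int = 1,
) -> ExamSpec:
    """Draw a reproducible :class:`ExamSpec` from the configured bands.

    The MTF item count is ``round(fraction * n_items)``, so a pinned
    fraction is honoured to within rounding (half an item).
    """
    rng = np.random.default_rng(seed)
    k_lo, k_hi = _as_band(config.n_items, "n_items")
    k = int(rng.integers(int(k_lo), int(k_hi) + 1))
    frac = _draw_truncnorm(
        rng,
        config.mtf_fraction_mean,
        config.mtf_fraction_sd,
        _as_band(config.mtf_fraction, "mtf_fraction"),
    )
    n_mtf = int(round(frac * k))
    mtf_positions = set(rng.choice(k, size=n_mtf, replace=False).tolist())
    cut = _draw_truncnorm(
        rng,
        config.cut_percent_mean,
        config.cut_percent_sd,
        _as_band(config.cut_percent, "cut_percent"),
    )
    locations = rng.normal(config.difficulty_mean, config.difficulty_sd, size=k)
    spread_band = _as_band(config.mtf_step_spread, "mtf_step_spread")
    width = len(str(k))
    items = []
    for j in range(k):
        item_id = f"i{j + 1:0{width}d}"
        if j in mtf_positions:
            spread = rng.uniform(*spread_band)
            steps = (locations[j] - spread / 2, locations[j] + spread / 2)
            items.append(ItemSpec(item_id, MTF, 4, steps))
        else:
            items.append(ItemSpec(item_id, TYPE_A, 5, (locations[j],)))
    return ExamSpec(
        exam_id=exam_id,
        items=tuple(items),
        cut_percent=cut,
        school=school,
        year_of_study=year_of_study,
    )


def draw_abilities(
    cohort: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sample abilities from the (possibly truncated) normal of the cohort."""
    if cohort.truncation_low is None and cohort.truncation_high is None:
        return rng.normal(cohort.ability_mean, cohort.ability_sd, cohort.n_examinees)
    lo = -np.inf if cohort.truncation_low is None else cohort.truncation_low
    hi = np.inf if cohort.truncation_high is None else cohort.truncation_high
    a = (lo - cohort.ability_mean) / cohort.ability_sd
    b = (hi - cohort.ability_mean) / cohort.ability_sd
    return stats.truncnorm.rvs(
        a, b,
        loc=cohort.ability_mean,
        scale=cohort.ability_sd,
        size=cohort.n_examinees,
        random_state=rng,
    )


def simulate_responses(
    exam: ExamSpec,
    cohort: CohortSpec,
    seed: int | np.random.SeedSequence,
) -> ResponseMatrix:
    """Simulate a scored response matrix under the partial credit model.

    Each examinee's ability is drawn from the cohort distribution; each
    item response is a draw from the PCM category probabilities at that
    ability, converted to points (categories x 0.5 for MTF items).
    """
    rng = np.random.default_rng(seed)
    theta = draw_abilities(cohort, rng)
    n = theta.size
    u = rng.random((n, exam.n_items))
    points = np.empty((n, exam.n_items))
    for j, item in enumerate(exam.items):
        probs = category_probs(np.asarray(item.step_params), theta)  # (n, C)
        cum = np.cumsum(probs, axis=1)
        cat = (u[:, j : j + 1] > cum[:, :-1]).sum(axis=1)
        points[:, j] = cat * item.point_weight
    width = len(str(n))
    examinee_ids = [f"p{v + 1:0{width}d}" for v in range(n)]
    frame = pd.DataFrame(points, index=examinee_ids, columns=exam.item_ids)
    return ResponseMatrix(frame, list(exam.item_kinds))


@dataclass
class StudyData:
    """A generated multi-exam study: specs, response matrices, manifest."""

    config: StudyGeneratorConfig
    exams: list[ExamSpec]
    responses: list[ResponseMatrix]
    manifest: pd.DataFrame

    def __iter__(self) -> Iterator[tuple[ExamSpec, ResponseMatrix]]:
        return iter(zip(self.exams, self.responses))

    def __len__(self) -> int:
        return len(self.exams)


def generate_study(
    config: StudyGeneratorConfig, seed: int | np.random.SeedSequence
) -> StudyData:
    """Generate the full study: one spec and response matrix per exam.

    Study years cycle deterministically over the configured years so the
    year-linked range restriction is represented evenly; schools are
    drawn uniformly.  Child seeds are spawned from ``seed`` so the study
    is reproducible as a whole.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(2 * config.n_exams)
    n_lo, n_hi = _as_band(config.n_examinees, "n_examinees")
    exams: list[ExamSpec] = []
    matrices: list[ResponseMatrix] = []
    rows = []
    for e in range(config.n_exams):
        year = config.years[e % len(config.years)]
        school = str(rng.choice(list(config.schools)))
        exam_id = f"exam{e + 1:02d}"
        exam = generate_exam_spec(
            config.exam,
            children[2 * e],
            exam_id=exam_id,
            school=school,
            year_of_study=year,
        )
        n_examinees = int(rng.integers(int(n_lo), int(n_hi) + 1))
        cohort = config.cohort_for_year(year, n_examinees)
        matrix = simulate_responses(exam, cohort, children[2 * e + 1])
        exams.append(exam)
        matrices.append(matrix)
        rows.append(
            {
                "exam_id": exam_id,
                "school": school,
                "year_of_study": year,
                "n_examinees": n_examinees,
                "n_items": exam.n_items,
                "pct_mtf": exam.pct_mtf,
                "cut_percent": exam.cut_percent,
                "max_points": exam.max_points,
            }
        )
    manifest = pd.DataFrame(rows).set_index("exam_id")
    return StudyData(config, exams, matrices, manifest)
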