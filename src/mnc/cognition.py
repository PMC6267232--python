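"""Cognitive z-scores against matched controls, domain composites, impairment.

Raw test scores are standardized against the mean and SD of the matched
healthy-control stratum and oriented so that higher z always means better
performance: for tests where a higher raw score is worse (e.g. completion
times) the z-score is negated.  Test z-scores are averaged (unweighted)
into six domain composites, and a domain is flagged impaired when its
composite lies at or below 1.5 SD under the control mean (z <= -1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io import CognitiveTable

IMPAIRMENT_THRESHOLD = -1.5

DOMAINS: tuple[str, ...] = (
    "executive",
    "psychomotor_speed",
    "working_memory",
    "information_processing",
    "attention",
    "verbal_memory",
)

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


@dataclass(frozen=True)
class TestSpec:
    """One test of the battery: its domain and score orientation."""

    name: str
    domain: str
    orientation: str = HIGHER_BETTER

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_BETTER, LOWER_BETTER):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")


#: packaged default battery: one synthetic test per domain; two are timed
#: (lower raw = better) to exercise the orientation rule
DEFAULT_BATTERY: tuple[TestSpec, ...] = (
    TestSpec("concept_shifting_time", "executive", LOWER_BETTER),
    TestSpec("motor_tapping", "psychomotor_speed", HIGHER_BETTER),
    TestSpec("digit_span", "working_memory", HIGHER_BETTER),
    TestSpec("letter_digit_substitution", "information_processing", HIGHER_BETTER),
    TestSpec("stroop_interference_time", "attention", LOWER_BETTER),
    TestSpec("word_list_recall", "verbal_memory", HIGHER_BETTER),
)


@dataclass(frozen=True)
class CognitiveProfile:
    subject_id: str
    domain_z: dict[str, float]
    impaired: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.domain_z) != set(DOMAINS):
            raise ValidationError("profile must cover exactly the six domains")


def zscore(
    raw: float,
    control_mean: float,
    control_sd: float,
    orientation: str = HIGHER_BETTER,
) -> float:
    """Standardize a raw score against its matched-control norm.

    Oriented so higher = better: lower-is-better tests are negated.
    """
    if control_sd <= 0:
        raise ValidationError(f"control_sd must be > 0, got {control_sd}")
    z = (raw - control_mean) / control_sd
    if orientation == LOWER_BETTER:
        z = -z
    elif orientation != HIGHER_BETTER:
        raise ValidationError(f"unknown orientation {orientation!r}")
    return z


def domain_composite(
    test_z: dict[str, float], mapping: dict[str, list[str]]
) -> dict[str, float]:
    """Unweighted mean of member-test z-scores per domain."""
    out: dict[str, float] = {}
    for domain, tests in mapping.items():
        missing = [t for t in tests if t not in test_z]
        if missing:
            raise ValidationError(f"domain {domain!r} missing test z-scores: {missing}")
        if not tests:
            raise ValidationError(f"domain {domain!r} maps to no tests")
        out[domain] = sum(test_z[t] for t in tests) / len(tests)
    return out


def battery_mapping(battery: tuple[TestSpec, ...]) -> dict[str, list[str]]:
    mapping: dict[str, list[str]] = {d: [] for d in DOMAINS}
    for spec in battery:
        mapping[spec.domain].append(spec.name)
    return {d: tests for d, tests in mapping.items() if tests}


def profile_subject(
    subject_id: str,
    raw_scores: dict[str, float],
    table: CognitiveTable,
    battery: tuple[TestSpec, ...] = DEFAULT_BATTERY,
) -> CognitiveProfile:
    """z-score each test against its control norm and compose the domains."""
    test_z: dict[str, float] = {}
    for spec in battery:
        if spec.name not in raw_scores:
            raise ValidationError(f"subject {subject_id}: missing test {spec.name!r}")
        mean, sd = table.norm_for(spec.name)
        test_z[spec.name] = zscore(raw_scores[spec.name], mean, sd, spec.orientation)
    domain_z = domain_composite(test_z, battery_mapping(battery))
    if set(domain_z) != set(DOMAINS):
        raise ValidationError("battery does not cover all six domains")
    impaired = {d: z <= IMPAIRMENT_THRESHOLD for d, z in domain_z.items()}
    return CognitiveProfile(subject_id=subject_id, domain_z=domain_z, impaired=impaired)
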