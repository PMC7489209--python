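"""Health states of the gastric carcinogenesis cascade.

The disease model follows the Correa cascade for non-cardia intestinal-type
gastric adenocarcinoma: normal mucosa progresses through atrophic gastritis,
intestinal metaplasia and dysplasia into preclinical (asymptomatic,
screen-detectable) cancer, which advances local -> regional -> distant until
it surfaces clinically through symptoms or is found at screening.

States are small integers so that population state can live in compact numpy
arrays; the :class:`HealthState` enum is the public face of the same codes.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """Ordered health states of the natural-history chain."""

    NORMAL = 0
    ATROPHIC_GASTRITIS = 1
    INTESTINAL_METAPLASIA = 2
    DYSPLASIA = 3
    PRECLINICAL_LOCAL = 4
    PRECLINICAL_REGIONAL = 5
    PRECLINICAL_DISTANT = 6
    CLINICAL_LOCAL = 7
    CLINICAL_REGIONAL = 8
    CLINICAL_DISTANT = 9
    #: Post-resection follow-up after complete endoscopic submucosal
    #: dissection of dysplasia.  In the simulation engine this is represented
    #: as INTESTINAL_METAPLASIA plus a positive surveillance counter; the enum
    #: member exists so the state can be named in reports.
    POST_ESD_SURVEILLANCE = 10
    DEAD_OTHER = 11
    DEAD_GC = 12


# Stage codes used wherever only the cancer stage matters.
LOCAL, REGIONAL, DISTANT = 0, 1, 2
STAGE_NAMES = ("local", "regional", "distant")

# States that a screening endoscopy with biopsy can find (true-positive
# states): dysplasia and any preclinical cancer.
LESION_STATES = frozenset(
    {
        HealthState.DYSPLASIA,
        HealthState.PRECLINICAL_LOCAL,
        HealthState.PRECLINICAL_REGIONAL,
        HealthState.PRECLINICAL_DISTANT,
    }
)

PRECLINICAL_STATES = (
    HealthState.PRECLINICAL_LOCAL,
    HealthState.PRECLINICAL_REGIONAL,
    HealthState.PRECLINICAL_DISTANT,
)
CLINICAL_STATES = (
    HealthState.CLINICAL_LOCAL,
    HealthState.CLINICAL_REGIONAL,
    HealthState.CLINICAL_DISTANT,
)

# Allowed forward edges of the chain (treatment-induced moves excluded).
FORWARD_EDGES = frozenset(
    {
        (HealthState.NORMAL, HealthState.ATROPHIC_GASTRITIS),
        (HealthState.ATROPHIC_GASTRITIS, HealthState.INTESTINAL_METAPLASIA),
        (HealthState.INTESTINAL_METAPLASIA, HealthState.DYSPLASIA),
        (HealthState.DYSPLASIA, HealthState.PRECLINICAL_LOCAL),
        (HealthState.PRECLINICAL_LOCAL, HealthState.PRECLINICAL_REGIONAL),
        (HealthState.PRECLINICAL_REGIONAL, HealthState.PRECLINICAL_DISTANT),
        (HealthState.PRECLINICAL_LOCAL, HealthState.CLINICAL_LOCAL),
        (HealthState.PRECLINICAL_REGIONAL, HealthState.CLINICAL_REGIONAL),
        (HealthState.PRECLINICAL_DISTANT, HealthState.CLINICAL_DISTANT),
    }
)


def stage_of(state: HealthState) -> int:
    """Cancer stage (LOCAL/REGIONAL/DISTANT) of a pre- or clinical state."""
    if state in (HealthState.PRECLINICAL_LOCAL, HealthState.CLINICAL_LOCAL):
        return LOCAL
    if state in (HealthState.PRECLINICAL_REGIONAL, HealthState.CLINICAL_REGIONAL):
        return REGIONAL
    if state in (HealthState.PRECLINICAL_DISTANT, HealthState.CLINICAL_DISTANT):
        return DISTANT
    raise ValueError(f"state {state!r} has no cancer stage")


MALE, FEMALE = 0, 1
SEX_NAMES = ("male", "female")

# Causes of death.
CAUSE_NONE, CAUSE_OTHER, CAUSE_GC = 0, 1, 2
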