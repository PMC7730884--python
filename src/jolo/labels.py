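"""Label vocabulary shared across the pipeline."""

ACTIVITIES = (
    "walking",
    "ascending_stairs",
    "descending_stairs",
    "sit_to_stand",
    "stand_to_sit",
    "jogging",
    "cycling",
)
"""The seven activity classes the classifier distinguishes."""

UNKNOWN = "unknown"
"""Reject-option label: prediction withheld because the classifier was uncertain."""

SITTING_OR_STANDING = "sitting_or_standing"
"""Phone-at-rest label; sitting and standing cannot be told apart under free orientation."""

LABEL_VOCABULARY = ACTIVITIES + (UNKNOWN, SITTING_OR_STANDING)

CYCLIC_ACTIVITIES = ("walking", "ascending_stairs", "descending_stairs", "jogging", "cycling")
"""Activities counted in cycles (strides or pedal rotations) via cadence estimation."""

TRANSITION_ACTIVITIES = ("sit_to_stand", "stand_to_sit")
"""One-off postural transitions counted as repetitions, not cycles."""
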