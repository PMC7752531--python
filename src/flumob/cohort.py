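"""Analysis-cohort construction: registration and background-survey exclusions."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ExclusionLog:
    n_input: int
    n_registration_incomplete: int
    n_background_incomplete: int
    n_retained: int

    def __post_init__(self):
        assert (
            self.n_registration_incomplete
            + self.n_background_incomplete
            + self.n_retained
            == self.n_input
        )


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop participants who never completed registration, then those missing
    the background survey; roster order is preserved.

    Exclusion order matters only for the per-reason counts: a participant
    failing both criteria is counted under incomplete registration.
    """
    n_input = len(roster)
    registered = roster[roster["registration_complete"]]
    n_reg = n_input - len(registered)
    cohort = registered[registered["background_complete"]]
    n_bg = len(registered) - len(cohort)
    log = ExclusionLog(
        n_input=n_input,
        n_registration_incomplete=n_reg,
        n_background_incomplete=n_bg,
        n_retained=len(cohort),
    )
    return cohort.reset_index(drop=True), log
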