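"""Study design: sample groups, the escalation-of-consumption code, drinking.

The design mirrors a three-group chronic-intermittent-ethanol (CIE) drinking
study: ethanol-naive mice, air-exposed two-bottle-choice drinkers (Air-2BC),
and vapor-exposed dependent drinkers (CIE-2BC). The ordinal
"escalation of consumption" (EoC) trait codes the groups 0 / 1 / 2 and is the
primary sample covariate used for module-trait correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

#: canonical group names, in EoC order
GROUPS = ("Naive", "Air2BC", "CIE2BC")

#: ordinal escalation-of-consumption code per group
EOC_CODE = {"Naive": 0, "Air2BC": 1, "CIE2BC": 2}

#: g/kg drinking scale per EoC unit used by the simulator (two-bottle-choice
#: limited-access intakes of dependent mice are in the 2.5-4 g/kg range)
DRINKING_SCALE = 1.75


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample group labels, EoC codes and average drinking amounts.

    ``table`` has one row per sample with columns ``sample_id``, ``group``,
    ``eoc`` and ``drinking`` (g/kg, average of the final 5-day two-bottle
    choice session; 0 for naive animals).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "eoc", "drinking"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidDesignError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise InvalidDesignError("duplicate sample IDs in design")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise InvalidDesignError(f"unknown group labels: {sorted(bad)}")
        if not set(self.table["eoc"]).issubset({0, 1, 2}):
            raise InvalidDesignError("eoc codes must be in {0, 1, 2}")
        if (self.table["drinking"] < 0).any():
            raise InvalidDesignError("drinking amounts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    @property
    def eoc(self) -> pd.Series:
        """Ordinal EoC trait (0 naive, 1 Air-2BC, 2 CIE-2BC), indexed by sample."""
        return self.table.set_index("sample_id")["eoc"].astype(float)

    @property
    def drinking(self) -> pd.Series:
        return self.table.set_index("sample_id")["drinking"].astype(float)

    @property
    def n_samples(self) -> int:
        return len(self.table)


def generate_design(n_per_group: int = 7, seed: int = 0) -> StudyDesign:
    """Generate a balanced three-group design with simulated drinking amounts.

    Drinking is ``eoc + Normal(0, 0.3)`` rescaled to g/kg and clipped at zero,
    so it is strongly but not perfectly correlated with the EoC code; naive
    animals drink exactly 0.

    Parameters
    ----------
    n_per_group:
        Samples per group (the reference design uses 7, i.e. 21 in total).
    seed:
        Seed for the drinking-noise generator; identical seeds give
        identical designs.
    """
    if n_per_group < 2:
        raise InvalidDesignError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        eoc = EOC_CODE[group]
        for i in range(n_per_group):
            if eoc == 0:
                drinking = 0.0
            else:
                drinking = max(eoc + rng.normal(0.0, 0.3), 0.0) * DRINKING_SCALE
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "eoc": eoc,
                    "drinking": drinking,
                }
            )
    return StudyDesign(pd.DataFrame(rows))
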