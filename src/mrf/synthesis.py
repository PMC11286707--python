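"""Seeded synthetic data: Delphi response matrices and patient medication lists.

Because no raw panel responses are published, every consumer of the consensus
engine and the scorer is exercised against generated data with controlled
structure. The response generator draws each (item, panellist) cell
independently from a categorical distribution over the 1-5 scale — mirroring an
anonymous panel with no cross-talk — parameterised either by an explicit
distribution or by a target agreement probability ``p_agree`` (the probability
of a 4 or 5). The medication-list generator draws drug names from the catalog
without replacement under a requested tier mix, so a realized list's score is
exactly 3*n_high + 2*n_moderate + 1*n_low and its expectation has the closed
form n*(3*p_high + 2*p_moderate + p_low).

No rater correlation, learning across rounds, or attrition is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import MrfCatalog
from .delphi import LikertMatrix

__all__ = [
    "ConsensusProfile",
    "generate_responses",
    "generate_med_list",
    "UNKNOWN_DRUG_POOL",
]


@dataclass(frozen=True)
class ConsensusProfile:
    """Target response distribution for generated Delphi panels.

    ``probs`` are the categorical probabilities of responses 1..5. The default
    panel size matches the validation study (22 experts). ``missing_rate`` is
    the independent probability that any cell is left blank.
    """

    probs: tuple[float, float, float, float, float]
    n_panellists: int = 22
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("probs must be 5 non-negative values summing to 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(
                "missing_rate must be in [0, 1); a profile with all mass on "
                "missing is degenerate"
            )
        if self.n_panellists < 1:
            raise ValueError("n_panellists must be >= 1")

    @property
    def p_agree(self) -> float:
        """Probability of a response of 4 or 5."""
        return float(self.probs[3] + self.probs[4])

    @classmethod
    def from_agreement(
        cls,
        p_agree: float,
        n_panellists: int = 22,
        missing_rate: float = 0.0,
        seed: int = 0,
    ) -> "ConsensusProfile":
        """Build a profile targeting a given agreement probability.

        The agreeing mass is split evenly between 4 and 5; the remainder is
        spread over 1..3 with most weight on Neutral (1: 20%, 2: 30%, 3: 50%
        of the disagreeing mass), the shape typical of expert panels drifting
        toward the midpoint rather than strong disagreement.
        """
        if not (0 <= p_agree <= 1):
            raise ValueError("p_agree must be in [0, 1]")
        d = 1.0 - p_agree
        probs = (0.2 * d, 0.3 * d, 0.5 * d, 0.5 * p_agree, 0.5 * p_agree)
        return cls(probs=probs, n_panellists=n_panellists,
                   missing_rate=missing_rate, seed=seed)


def generate_responses(profile: ConsensusProfile, n_items: int) -> LikertMatrix:
    """Generate an items x panellists Likert matrix from a consensus profile.

    A single pseudorandom stream keyed by ``profile.seed`` drives both the
    categorical draws and the missingness mask, so a fixed seed yields a
    bit-identical matrix.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(profile.seed)
    shape = (n_items, profile.n_panellists)
    values = rng.choice([1, 2, 3, 4, 5], size=shape, p=profile.probs).astype(float)
    if profile.missing_rate > 0:
        mask = rng.random(shape) < profile.missing_rate
        # keep at least one response per item so statistics stay defined
        full_rows = mask.all(axis=1)
        if full_rows.any():
            keep = rng.integers(0, profile.n_panellists, size=int(full_rows.sum()))
            mask[np.flatnonzero(full_rows), keep] = False
        values[mask] = np.nan
    df = pd.DataFrame(
        values,
        index=[f"item_{i + 1:04d}" for i in range(n_items)],
        columns=[f"panellist_{j + 1:02d}" for j in range(profile.n_panellists)],
    )
    return LikertMatrix(df)


#: Medications deliberately outside the catalog's 19 classes, for exercising
#: the unresolved path (real lists routinely contain such drugs).
UNKNOWN_DRUG_POOL: tuple[str, ...] = (
    "ascorbic acid", "paracetamol", "cetirizine", "omeprazole", "simvastatin",
    "levothyroxine", "metformin", "salbutamol", "folic acid", "colecalciferol",
    "alendronic acid", "ferrous sulfate tablets", "aspirin", "clopidogrel",
    "ranitidine", "loratadine",
)


def generate_med_list(
    catalog: MrfCatalog,
    n_meds: int,
    tier_mix: Mapping[str, float],
    seed: int = 0,
) -> list[str]:
    """Draw a synthetic patient medication list with a controlled tier mix.

    ``tier_mix`` gives proportions over {high, moderate, low, unknown} summing
    to 1. Tier counts are drawn multinomially, then distinct generic names are
    sampled without replacement within each tier (unknown drugs come from a
    fixed pool outside the catalog), and the combined list is shuffled.
    Requesting a tier for which the catalog has no members is an error, as is
    asking for more drugs than a tier's distinct pool can supply.
    """
    if n_meds < 0:
        raise ValueError("n_meds must be >= 0")
    mix = {k: float(v) for k, v in tier_mix.items() if v}
    unknown_tiers = set(mix) - {"high", "moderate", "low", "unknown"}
    if unknown_tiers:
        raise ValueError(f"unknown tiers in tier_mix: {sorted(unknown_tiers)}")
    probs = np.array(list(mix.values()), dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("tier_mix proportions must be >= 0 and sum to 1")
    if n_meds == 0:
        return []
    rng = np.random.default_rng(seed)
    tiers = list(mix)
    counts = rng.multinomial(n_meds, probs / probs.sum())
    names: list[str] = []
    for tier, k in zip(tiers, counts):
        if k == 0:
            continue
        pool = (
            list(UNKNOWN_DRUG_POOL)
            if tier == "unknown"
            else catalog.members_of_tier(tier)
        )
        if not pool:
            raise ValueError(f"catalog has no members in tier {tier!r}")
        if k > len(pool):
            raise ValueError(
                f"requested {k} distinct {tier!r} drugs but only "
                f"{len(pool)} are available"
            )
        names.extend(rng.choice(pool, size=int(k), replace=False).tolist())
    rng.shuffle(names)
    return names
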