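"""Option-bias randomization test for group-level behavioural traditions.

If social learning maintains traditions, groups should be
disproportionately biased toward one of the task options relative to the
population as a whole.  The test statistic is the group-size-weighted
sum of absolute deviations of each group's option proportion from the
pooled proportion,

    T = sum_g n_g * | p_g - p_pooled |,

computed on counts of either individuals (each unit is one animal,
classified by the option it used) or manipulations (each unit is one
bout).  The null distribution is generated by reallocating every unit's
option independently at random with probability equal to the pooled
proportion, preserving group sizes; the Monte-Carlo p-value uses the
add-one correction p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OptionCountTable", "option_bias_statistic", "option_bias_test",
           "OptionBiasResult"]


@dataclass
class OptionCountTable:
    """Per-group counts of units using each option-type.

    ``seeded_option`` records which option the group's demonstrator was
    trained on ("flap", "tube" or "none" for control groups); groups with
    no seeded option can be excluded from the test by flag.
    """

    table: pd.DataFrame  # columns: group, n_flap, n_tube, seeded_option

    @classmethod
    def from_counts(cls, groups, n_flap, n_tube,
                    seeded_option=None) -> "OptionCountTable":
        n = len(groups)
        seeded = list(seeded_option) if seeded_option is not None \
            else ["none"] * n
        return cls(pd.DataFrame({"group": list(groups),
                                 "n_flap": list(n_flap),
                                 "n_tube": list(n_tube),
                                 "seeded_option": seeded}))

    @classmethod
    def from_event_log(cls, log, unit: str = "individuals",
                       solvers_only: bool = False) -> "OptionCountTable":
        """Tabulate an event log, excluding demonstrators.

        ``unit="individuals"`` counts each non-demonstrator once per
        option-type it manipulated (an individual using both options
        contributes to both counts, as in proportion-of-individuals
        summaries); ``unit="manipulations"`` counts bouts.
        ``solvers_only`` restricts to successful bouts/solvers.
        """
        inds = log._ind_index()
        seeded = {}
        for i in log.individuals:
            seeded.setdefault(i.group_id, "none")
            if i.is_demonstrator and i.trained_option_type:
                seeded[i.group_id] = i.trained_option_type
        used: dict[tuple[str, str], set | int] = {}
        for g in sorted(seeded):
            for k in ("flap", "tube"):
                used[(g, k)] = set() if unit == "individuals" else 0
        for b in log.bouts:
            ind = inds[b.individual_id]
            if ind.is_demonstrator or b.option_type not in ("flap", "tube"):
                continue
            if solvers_only and b.outcome != "solved":
                continue
            key = (ind.group_id, b.option_type)
            if unit == "individuals":
                used[key].add(ind.id)
            else:
                used[key] += 1
        groups = sorted(seeded)
        count = (len if unit == "individuals" else int)
        return cls.from_counts(
            groups,
            [count(used[(g, "flap")]) for g in groups],
            [count(used[(g, "tube")]) for g in groups],
            [seeded[g] for g in groups])

    def restrict_to_seeded(self) -> "OptionCountTable":
        t = self.table[self.table["seeded_option"] != "none"]
        return OptionCountTable(t.reset_index(drop=True))


@dataclass(frozen=True)
class OptionBiasResult:
    statistic: float
    p_value: float
    n_perm: int
    unit: str
    pooled_proportion: float


def option_bias_statistic(n_flap: np.ndarray, n_total: np.ndarray) -> float:
    """Group-size-weighted absolute deviation from the pooled proportion."""
    n_flap = np.asarray(n_flap, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if (n_total <= 0).any():
        raise ValueError("every group must contribute at least one unit")
    pooled = n_flap.sum() / n_total.sum()
    return float(np.sum(n_total * np.abs(n_flap / n_total - pooled)))


def option_bias_test(table: OptionCountTable, unit: str = "individuals",
                     n_perm: int = 9999, seed: int | None = None,
                     include_unseeded: bool = True) -> OptionBiasResult:
    """Monte-Carlo option-bias test on a group x option count table.

    Requires at least two groups and ``n_perm >= 999``.  The resampling
    unit (individuals or manipulations) is whatever the counts represent;
    the flag is recorded in the result.  Deterministic given *seed*.
    """
    if unit not in ("individuals", "manipulations"):
        raise ValueError("unit must be 'individuals' or 'manipulations'")
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    t = table.table if include_unseeded else \
        table.restrict_to_seeded().table
    if len(t) < 2:
        raise ValueError("need at least two groups")
    n_flap = t["n_flap"].to_numpy(dtype=float)
    n_total = n_flap + t["n_tube"].to_numpy(dtype=float)
    if (n_total <= 0).any():
        raise ValueError("every group must contribute at least one unit")
    observed = option_bias_statistic(n_flap, n_total)
    pooled = n_flap.sum() / n_total.sum()
    rng = np.random.default_rng(seed)
    perm_flap = rng.binomial(n_total.astype(int)[None, :].repeat(n_perm, 0),
                             pooled)
    perm_pooled = perm_flap.sum(axis=1) / n_total.sum()
    perm_stats = np.sum(
        n_total[None, :] * np.abs(perm_flap / n_total[None, :] -
                                  perm_pooled[:, None]), axis=1)
    p = (1.0 + np.sum(perm_stats >= observed)) / (1.0 + n_perm)
    return OptionBiasResult(statistic=observed, p_value=float(p),
                            n_perm=n_perm, unit=unit,
                            pooled_proportion=float(pooled))
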