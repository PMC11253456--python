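"""Published descriptive counts from the reference CBHI household survey.

A community-based cross-sectional survey of 825 household heads in Debre
Tabor town (Northwest Ethiopia, 2022) is the study whose design this
package's defaults emulate: 194 insured and 631 non-insured households,
overall CHE headcount 247/825 at the 10% threshold.  The marginal counts
(``TABLE1_MARGINALS``) and the per-insurance-stratum cross-tabulated counts
(``TABLE2_BY_INSURANCE``) below are used as default covariate marginals for
the synthetic generator and as integer-arithmetic benchmark fixtures.

Note: the published CHE-by-insurance cross counts (46/201 insured,
148/430 non-insured) imply a CHE-yes total of 194, while the marginal
table prints 247; the two tables are reported here exactly as printed and
are not reconciled.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np

from .survey import ExpenditureProfile, HouseholdRecord

__all__ = [
    "N_TOTAL",
    "N_INSURED",
    "N_NON_INSURED",
    "TABLE1_MARGINALS",
    "TABLE2_BY_INSURANCE",
    "CHE_BY_INSURANCE",
    "marginal_probabilities",
    "records_from_marginals",
    "records_from_che_insurance_cross",
]

N_TOTAL = 825
N_INSURED = 194
N_NON_INSURED = 631

#: Marginal category counts over the full analytic sample (n = 825).
TABLE1_MARGINALS: dict[str, dict[str, int]] = {
    "head_sex": {"male": 574, "female": 251},
    "head_age_group": {"<=30": 191, "31-45": 343, "46-60": 182, ">60": 109},
    "marital_status": {
        "single": 55, "married": 573, "separated": 28, "divorced": 74, "widowed": 95,
    },
    "ownership": {"private": 521, "rent": 304},
    "occupation": {"self_employed": 399, "government": 385, "private_sector": 41},
    "family_size_group": {"<=4": 628, ">4": 197},
    "u5_present": {"yes": 261, "no": 564},
    "wealth": {"poorest": 163, "poorer": 160, "middle": 161, "richer": 179, "richest": 162},
    "chronic_condition": {"yes": 249, "no": 576},
    "traditional_medicine": {"yes": 178, "no": 647},
    "referral_history": {"yes": 41, "no": 654, "missing": 130},
    "che": {"yes": 247, "no": 578},
    "insurance": {"insured": 194, "non_insured": 631},
}

#: Category counts per insurance stratum (columns sum to 194 / 631).
TABLE2_BY_INSURANCE: dict[str, dict[str, dict[str, int]]] = {
    "head_sex": {
        "insured": {"male": 127, "female": 67},
        "non_insured": {"male": 447, "female": 184},
    },
    "head_age_group": {
        "insured": {"<=30": 33, "31-45": 73, "46-60": 56, ">60": 32},
        "non_insured": {"<=30": 158, "31-45": 270, "46-60": 126, ">60": 77},
    },
    "marital_status": {
        "insured": {"single": 18, "married": 116, "separated": 5, "divorced": 20, "widowed": 35},
        "non_insured": {"single": 37, "married": 457, "separated": 23, "divorced": 54, "widowed": 60},
    },
    "u5_present": {
        "insured": {"yes": 61, "no": 133},
        "non_insured": {"yes": 200, "no": 431},
    },
    "family_size_group": {
        "insured": {"<=4": 143, ">4": 51},
        "non_insured": {"<=4": 485, ">4": 146},
    },
    "occupation": {
        "insured": {"self_employed": 158, "government": 19, "private_sector": 17},
        "non_insured": {"self_employed": 241, "government": 366, "private_sector": 24},
    },
    "wealth": {
        "insured": {"poorest": 67, "poorer": 52, "middle": 29, "richer": 26, "richest": 20},
        "non_insured": {"poorest": 96, "poorer": 108, "middle": 132, "richer": 153, "richest": 142},
    },
    "ownership": {
        "insured": {"private": 125, "rent": 69},
        "non_insured": {"private": 396, "rent": 235},
    },
    "chronic_condition": {
        "insured": {"yes": 70, "no": 124},
        "non_insured": {"yes": 179, "no": 452},
    },
    "traditional_medicine": {
        "insured": {"yes": 35, "no": 159},
        "non_insured": {"yes": 143, "no": 488},
    },
}

#: CHE (yes, no) counts by insurance stratum, as printed.
CHE_BY_INSURANCE: dict[str, tuple[int, int]] = {
    "insured": (46, 201),
    "non_insured": (148, 430),
}

#: CHE (yes, no) counts by household-head sex, as printed.
CHE_BY_SEX: dict[str, tuple[int, int]] = {
    "male": (187, 387),
    "female": (60, 191),
}


def marginal_probabilities(group: str) -> dict[str, dict[str, float]]:
    """Per-covariate category probabilities for one insurance stratum."""
    out = {}
    for var, groups in TABLE2_BY_INSURANCE.items():
        counts = groups[group]
        total = sum(counts.values())
        out[var] = {level: c / total for level, c in counts.items()}
    return out


_AGE_RANGES = {"<=30": (18, 30), "31-45": (31, 45), "46-60": (46, 60), ">60": (61, 90)}

#: Expenditure profiles that encode a CHE flag unambiguously at the 10%
#: total-budget threshold: shares 0.25 (flagged) and 0.02 (not flagged).
_PROFILE_CHE = ExpenditureProfile(
    food=45000.0, nonfood_nonhealth=15000.0, direct_medical=18000.0,
    direct_nonmedical=2000.0, lost_days=0.0, daily_valuation=0.0,
)
_PROFILE_NO_CHE = ExpenditureProfile(
    food=45000.0, nonfood_nonhealth=33775.5, direct_medical=1500.0,
    direct_nonmedical=108.5, lost_days=0.0, daily_valuation=0.0,
)


def profile_for_flag(flagged: bool) -> ExpenditureProfile:
    """An expenditure profile whose 10%-threshold CHE flag equals ``flagged``."""
    return _PROFILE_CHE if flagged else _PROFILE_NO_CHE


def _spread(levels: Mapping[str, int], n: int, rng: np.random.Generator) -> list[str]:
    values = list(
        itertools.chain.from_iterable([lvl] * c for lvl, c in levels.items())
    )
    if len(values) != n:
        raise ValueError(f"counts sum to {len(values)}, expected {n}")
    rng.shuffle(values)
    return values


def records_from_marginals(
    marginals: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
) -> list[HouseholdRecord]:
    """Build a record collection matching given marginal counts exactly.

    Each variable's categories are assigned independently of the others
    (the joint distribution is arbitrary); only marginal tabulations of the
    result are meaningful.  Defaults to the published n=825 marginals.
    """
    marginals = dict(marginals or TABLE1_MARGINALS)
    n = sum(marginals["insurance"].values())
    rng = np.random.default_rng(seed)
    columns = {
        var: _spread(levels, n, rng)
        for var, levels in marginals.items()
    }
    records = []
    for i in range(n):
        age_lo, age_hi = _AGE_RANGES[columns["head_age_group"][i]]
        records.append(
            HouseholdRecord(
                household_id=f"hh{i:04d}",
                kebele="01",
                head_sex=columns["head_sex"][i],
                head_age=int(rng.integers(age_lo, age_hi + 1)),
                marital_status=columns["marital_status"][i],
                occupation=columns["occupation"][i],
                family_size=1 if columns["family_size_group"][i] == "<=4" else 5,
                u5_present=columns["u5_present"][i],
                ownership=columns["ownership"][i],
                insurance=columns["insurance"][i],
                chronic_condition=columns["chronic_condition"][i],
                traditional_medicine=columns["traditional_medicine"][i],
                referral_history=columns["referral_history"][i],
                expenditure=profile_for_flag(columns["che"][i] == "yes"),
            )
        )
    return records


def records_from_che_insurance_cross(
    cross: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> list[HouseholdRecord]:
    """Build records matching a CHE x insurance cross-count table exactly.

    Defaults to the published cross counts (46/201 insured, 148/430
    non-insured; n = 825).  All other fields take fixed defaults.
    """
    cross = dict(cross or CHE_BY_INSURANCE)
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for group, (n_yes, n_no) in cross.items():
        for flagged, count in ((True, n_yes), (False, n_no)):
            for _ in range(count):
                records.append(
                    HouseholdRecord(
                        household_id=f"hh{i:04d}",
                        kebele="01",
                        head_sex="male",
                        head_age=int(rng.integers(18, 80)),
                        marital_status="married",
                        occupation="self_employed",
                        family_size=3,
                        u5_present="no",
                        ownership="private",
                        insurance=group,
                        chronic_condition="no",
                        traditional_medicine="no",
                        referral_history="no",
                        expenditure=profile_for_flag(flagged),
                    )
                )
                i += 1
    return records
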