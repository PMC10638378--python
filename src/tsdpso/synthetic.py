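"""Synthetic clinical cohort generator for the diagnostic pipeline.

Emulates the structure of a fracture-related-infection (FRI) registry:
a balanced two-class table of mixed binary indicator features (bone
nonunion, pathogen cultures, sinus tract, pus discharge, ...) and
continuous features (age, serum inflammatory markers), 97 features by
default of which 22 carry class signal.  The class-separation dial
``delta`` shifts continuous informative means by ``delta`` standard
deviations and separates binary indicator rates by ``min(0.2*delta,
0.8)``.  Ages are drawn per age stratum with stratum totals following
the registry's published distribution (teenager 864/921, middle-aged
1766/1842, elderly 2131/1998 per class label).

A companion defect injector plants missing cells, duplicate rows and
extreme-valued rows at known indices so cleaning can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "DefectPlan", "generate_cohort", "inject_defects"]

# (age_low, age_high, FRI count, Non-FRI count) at the reference cohort size
_DEFAULT_STRATA: list[tuple[int, int, int, int]] = [
    (8, 34, 864, 921),
    (35, 65, 1766, 1842),
    (66, 100, 2131, 1998),
]

_INDICATOR_NAMES = [
    "nonunion_of_bone",
    "fracture",
    "staphylococcus_aureus",
    "pseudomonas_aeruginosa",
    "persistent_exudation",
    "hyperosteogeny",
    "bone_defect",
    "periosteal_reaction",
    "sinus",
    "fibrous_union",
    "discharge_pus",
    "trauma",
    "escherichia_coli",
    "implant_loosening",
]

_MARKER_NAMES = ["crp", "esr", "wbc", "il6", "pct", "lysozyme", "neutrophil_ratio"]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``n_informative`` counts age plus the signal-bearing binary and
    continuous features.  ``delta`` is the effect size: 0 removes all
    feature signal (age keeps only the mild stratum imbalance of the
    reference distribution).
    """

    n_per_class: int = 4761
    n_binary_features: int = 80
    n_continuous_features: int = 17  # includes age
    n_informative: int = 22
    delta: float = 1.0
    age_strata: list[tuple[int, int, int, int]] = field(
        default_factory=lambda: list(_DEFAULT_STRATA)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.n_continuous_features < 1:
            raise ValueError("need at least the age column")
        total = self.n_binary_features + self.n_continuous_features
        if not 1 <= self.n_informative <= total:
            raise ValueError("n_informative must be within the feature count")
        for lo, hi, f, n in self.age_strata:
            if lo > hi or f < 0 or n < 0:
                raise ValueError("invalid age stratum")


@dataclass
class DefectPlan:
    """Planted defect locations returned by :func:`inject_defects`."""

    missing_rows: list[int]
    duplicate_rows: list[int]
    outlier_rows: list[int]


def _allocate(counts: list[int], n: int) -> list[int]:
    """Largest-remainder allocation of n samples to strata proportions."""
    total = sum(counts)
    raw = [c * n / total for c in counts]
    out = [int(np.floor(r)) for r in raw]
    rem = n - sum(out)
    order = np.argsort([f - np.floor(f) for f in raw])[::-1]
    for i in order[:rem]:
        out[int(i)] += 1
    return out


def _binary_split(spec: CohortSpec) -> tuple[int, int]:
    """How many informative features are binary vs continuous (age aside)."""
    n_inf = spec.n_informative - 1  # age is always informative via strata
    n_bin = min(spec.n_binary_features, int(np.ceil(n_inf * 2 / 3)))
    n_cont = min(spec.n_continuous_features - 1, n_inf - n_bin)
    return n_bin, n_cont


def _feature_names(spec: CohortSpec) -> tuple[list[str], list[str]]:
    n_inf_bin, n_inf_cont = _binary_split(spec)
    bin_names = [
        _INDICATOR_NAMES[i] if i < len(_INDICATOR_NAMES) else f"indicator_{i:02d}"
        for i in range(spec.n_binary_features)
    ]
    cont_names = ["age"] + [
        _MARKER_NAMES[i] if i < len(_MARKER_NAMES) else f"marker_{i:02d}"
        for i in range(spec.n_continuous_features - 1)
    ]
    return bin_names, cont_names


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Balanced labeled cohort table; last column is the binary label "FRI"."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    n_inf_bin, n_inf_cont = _binary_split(spec)
    bin_names, cont_names = _feature_names(spec)

    rate_gap = min(0.2 * spec.delta, 0.8)
    base_rate = 0.15
    columns: dict[str, np.ndarray] = {}

    for j, name in enumerate(bin_names):
        if j < n_inf_bin:
            p0, p1 = base_rate, min(base_rate + rate_gap, 0.95)
        else:
            p0 = p1 = 0.3
        col0 = (rng.random(n) < p0).astype(int)
        col1 = (rng.random(n) < p1).astype(int)
        columns[name] = np.concatenate([col0, col1])

    # Ages per stratum; stratum totals follow the reference distribution.
    ages = {}
    for label, col in ((0, 3), (1, 2)):  # Non-FRI uses col 3, FRI col 2
        counts = [s[col] for s in spec.age_strata]
        alloc = _allocate(counts, n)
        parts = [
            rng.integers(lo, hi + 1, size=k)
            for (lo, hi, _, _), k in zip(spec.age_strata, alloc)
        ]
        a = np.concatenate(parts).astype(float)
        rng.shuffle(a)
        ages[label] = a
    columns["age"] = np.concatenate([ages[0], ages[1]])

    for j, name in enumerate(cont_names[1:]):
        shift = spec.delta if j < n_inf_cont else 0.0
        col0 = rng.normal(0.0, 1.0, n)
        col1 = rng.normal(shift, 1.0, n)
        columns[name] = np.concatenate([col0, col1])

    columns["FRI"] = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    df = pd.DataFrame(columns)
    # Shuffle rows so class blocks are interleaved; keep a clean 0..N index.
    perm = rng.permutation(len(df))
    return df.iloc[perm].reset_index(drop=True)


def inject_defects(
    table: pd.DataFrame,
    missing_rate: float = 0.0,
    duplicate_rows: int = 0,
    outlier_rows: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, DefectPlan]:
    """Plant missing cells, duplicated rows and >=6-sigma outlier rows.

    The three defect sets are kept disjoint so a cleaning pass that drops
    missing rows, then duplicates, then z-score outliers reports exactly
    the planted counts.  Duplicates are appended at the end of the table.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if duplicate_rows < 0 or outlier_rows < 0:
        raise ValueError("defect counts must be non-negative")
    rng = np.random.default_rng(seed)
    df = table.copy()
    feature_cols = [c for c in df.columns if c != "FRI"]
    cont_cols = [
        c for c in feature_cols if df[c].nunique() > 2 and c != "age"
    ]
    n = len(df)

    n_missing = int(np.floor(missing_rate * n + 0.5))
    reserved = n_missing + outlier_rows + duplicate_rows
    if reserved > n:
        raise ValueError("too many defects for the table size")
    picks = rng.choice(n, size=reserved, replace=False)
    missing_idx = sorted(int(i) for i in picks[:n_missing])
    outlier_idx = sorted(int(i) for i in picks[n_missing : n_missing + outlier_rows])
    dup_src = sorted(int(i) for i in picks[n_missing + outlier_rows :])

    for i in missing_idx:
        col = feature_cols[int(rng.integers(len(feature_cols)))]
        df.loc[df.index[i], col] = np.nan

    if outlier_rows and not cont_cols:
        raise ValueError("no continuous column available for outlier planting")
    for i in outlier_idx:
        col = cont_cols[int(rng.integers(len(cont_cols)))]
        vals = table[col].to_numpy(dtype=float)
        df.loc[df.index[i], col] = vals.mean() + 8.0 * max(vals.std(), 1e-12)

    dup_positions = list(range(n, n + len(dup_src)))
    if dup_src:
        df = pd.concat([df, df.iloc[dup_src]], ignore_index=True)

    return df, DefectPlan(missing_idx, dup_positions, outlier_idx)
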