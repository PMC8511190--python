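"""Master-regulator activation calls from a signed causal network.

Given a regulator -> (target, sign) network and the observed per-protein
direction of change between two sample classes, each regulator receives an
activation z-score

    z = (N_consistent - N_inconsistent) / sqrt(N)

over its N informative targets (those with a nonzero observed direction),
where a target is consistent when edge sign times observed direction is +1.
Overlap significance between the regulator's target set and the analyzed
protein set uses a one-sided Fisher exact (hypergeometric) test. Calls use
the conventional thresholds: |z| >= 2 activated/inhibited, 1.5 < |z| < 2
up-/downregulated, gated at an overlap p-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CausalNetwork",
    "RegulatorCall",
    "direction_of_change",
    "activation_z",
    "overlap_p",
    "classify_regulator",
    "call_regulators",
]


@dataclass
class CausalNetwork:
    """Regulator -> list of (target protein, edge sign in {+1, -1})."""

    edges: dict[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        for reg, targets in self.edges.items():
            seen = set()
            for t, s in targets:
                if s not in (1, -1):
                    raise ValueError(f"edge sign must be +1/-1: {reg}->{t} ({s})")
                if t in seen:
                    raise ValueError(f"duplicate edge {reg}->{t}")
                seen.add(t)

    @property
    def regulators(self) -> list[str]:
        return list(self.edges)

    def targets(self, regulator: str) -> list[str]:
        return [t for t, _ in self.edges[regulator]]

    @classmethod
    def from_tsv(cls, path) -> "CausalNetwork":
        df = pd.read_csv(path, sep="\t")
        required = {"regulator", "target", "sign"}
        if not required.issubset(df.columns):
            raise ValueError(f"causal network TSV needs columns {sorted(required)}")
        edges: dict[str, list[tuple[str, int]]] = {}
        for row in df.itertuples(index=False):
            edges.setdefault(str(row.regulator), []).append(
                (str(row.target), int(row.sign))
            )
        return cls(edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"regulator": r, "target": t, "sign": s}
            for r, targets in self.edges.items()
            for t, s in targets
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "sign"])


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    n_targets_in_data: int
    z: float
    overlap_p: float
    state: str


def direction_of_change(
    X, traits, trait: str, min_abs_log_ratio: float = 0.0
) -> pd.Series:
    """Per-protein sign of the class-1 minus class-0 mean log2(count + 1).

    Differences smaller in magnitude than ``min_abs_log_ratio`` are set to
    0 (uninformative).
    """
    y = traits.traits[trait].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError(f"trait {trait!r} has a single class")
    logx = np.log2(X.values + 1.0)
    diff = logx[:, y == 1].mean(axis=1) - logx[:, y == 0].mean(axis=1)
    d = np.sign(diff).astype(int)
    d[np.abs(diff) < min_abs_log_ratio] = 0
    return pd.Series(d, index=X.protein_ids, name="direction")


def activation_z(net: CausalNetwork, d: pd.Series) -> pd.DataFrame:
    """Activation z-score per regulator over informative targets.

    Targets absent from ``d`` or with direction 0 are dropped; a regulator
    with no informative target gets z = 0 and n_targets = 0.
    """
    rows = []
    for reg, targets in net.edges.items():
        n_cons = n_incons = 0
        for t, s in targets:
            dt = int(d.get(t, 0))
            if dt == 0:
                continue
            if s * dt == 1:
                n_cons += 1
            else:
                n_incons += 1
        n = n_cons + n_incons
        z = (n_cons - n_incons) / np.sqrt(n) if n > 0 else 0.0
        rows.append({"regulator": reg, "n_targets_in_data": n, "z": float(z)})
    return pd.DataFrame(rows, columns=["regulator", "n_targets_in_data", "z"])


def overlap_p(net: CausalNetwork, dataset: set[str], background: set[str]) -> pd.Series:
    """One-sided Fisher exact overlap p per regulator.

    Tests over-representation of the regulator's targets (restricted to the
    background) inside the analyzed dataset, against the background
    universe: p = P(X >= observed) under the hypergeometric null.
    """
    dataset = set(dataset)
    background = set(background)
    stray = dataset - background
    if stray:
        raise ValueError(f"dataset not contained in background: {sorted(stray)[:5]}")
    N = len(background)
    n_draw = len(dataset)
    out = {}
    for reg in net.regulators:
        targets = set(net.targets(reg)) & background
        K = len(targets)
        obs = len(targets & dataset)
        if K == 0:
            out[reg] = 1.0
        else:
            out[reg] = float(hypergeom.sf(obs - 1, N, K, n_draw))
    return pd.Series(out, name="overlap_p")


def classify_regulator(z: float, p: float, p_max: float = 0.005) -> str:
    """Categorical activation state from the z-score and overlap p.

    z >= 2 counts as activated (the boundary is inclusive so that a score
    of exactly 2 lands in the activated class); symmetric for inhibition.
    """
    if p >= p_max:
        return "none"
    if z >= 2.0:
        return "activated"
    if 1.5 < z < 2.0:
        return "upregulated"
    if z <= -2.0:
        return "inhibited"
    if -2.0 < z < -1.5:
        return "downregulated"
    return "none"


def call_regulators(
    net: CausalNetwork,
    X,
    traits,
    trait: str,
    dataset: set[str] | None = None,
    background: set[str] | None = None,
    p_max: float = 0.005,
    min_abs_log_ratio: float = 0.0,
) -> pd.DataFrame:
    """End-to-end regulator calls for one binary trait.

    ``dataset`` defaults to all measured proteins and ``background`` to the
    union of the dataset and every network target. The overlap test stands
    in for the proprietary network-bias-corrected significance used by
    commercial causal-analysis tools; the z-score semantics are identical.
    """
    d = direction_of_change(X, traits, trait, min_abs_log_ratio)
    if dataset is None:
        dataset = set(X.protein_ids)
    if background is None:
        background = set(dataset)
        for reg in net.regulators:
            background |= set(net.targets(reg))
    zs = activation_z(net, d).set_index("regulator")
    ps = overlap_p(net, dataset, background)
    rows = []
    for reg in net.regulators:
        z = float(zs.loc[reg, "z"])
        p = float(ps[reg])
        rows.append(
            {
                "regulator": reg,
                "n_targets_in_data": int(zs.loc[reg, "n_targets_in_data"]),
                "z": z,
                "overlap_p": p,
                "state": classify_regulator(z, p, p_max),
            }
        )
    return pd.DataFrame(rows)
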