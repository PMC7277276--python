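"""Pair/triplet association scores on the periodic Delaunay mesh.

Adjacent lipids share a Delaunay edge (equivalently, a Voronoi boundary);
three mutually adjacent lipids form a mesh triangle.  The association
score of a species combination is its observed adjacency count divided by
the count expected when species labels are assigned at random, holding
the mesh geometry fixed: 1.0 is chance, > 1 favoured, < 1 disfavoured.
The expectation and its confidence band come from seeded random label
permutations on the observed mesh (an analytic label-frequency
approximation is also provided for cross-checks).
"""
from __future__ import annotations

from itertools import combinations_with_replacement
from math import factorial

import numpy as np
import pandas as pd

from .tessellation import PeriodicTessellation


def _encode(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cats = sorted(set(labels.tolist()))
    lut = {c: k for k, c in enumerate(cats)}
    return np.array([lut[x] for x in labels]), cats


def _pair_codes(lab: np.ndarray, edges: np.ndarray, k: int) -> np.ndarray:
    a = lab[edges[:, 0]]
    b = lab[edges[:, 1]]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return lo * k + hi


def _triplet_codes(lab: np.ndarray, tris: np.ndarray, k: int) -> np.ndarray:
    t = np.sort(lab[tris], axis=1)
    return (t[:, 0] * k + t[:, 1]) * k + t[:, 2]


def count_adjacencies(tess: PeriodicTessellation, labels) -> tuple[dict, dict]:
    """Observed pair and triplet adjacency counts per species combination.

    Every mesh edge contributes to exactly one unordered pair class and
    every triangle to one unordered triplet class, so the counts sum to
    the edge and triangle totals.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != tess.n_points:
        raise ValueError(
            f"labels ({len(labels)}) do not cover tessellation points ({tess.n_points})"
        )
    lab, cats = _encode(labels)
    k = len(cats)
    pairs: dict[tuple, int] = {}
    for code, n in zip(*np.unique(_pair_codes(lab, tess.edge_pairs, k), return_counts=True)):
        pairs[(cats[code // k], cats[code % k])] = int(n)
    trips: dict[tuple, int] = {}
    for code, n in zip(*np.unique(_triplet_codes(lab, tess.triangles, k), return_counts=True)):
        c0, rest = divmod(int(code), k)
        a, b = divmod(c0, k)
        trips[(cats[a], cats[b], cats[rest])] = int(n)
    return pairs, trips


def expected_counts_analytic(tess: PeriodicTessellation, labels) -> tuple[dict, dict]:
    """Closed-form expected counts from label frequencies (sampling with
    replacement approximation; accurate to O(1/n) for large n)."""
    labels = np.asarray(labels, dtype=object)
    lab, cats = _encode(labels)
    n = len(lab)
    freq = np.bincount(lab, minlength=len(cats)) / n
    n_e, n_t = len(tess.edge_pairs), len(tess.triangles)
    pairs = {}
    for a, b in combinations_with_replacement(range(len(cats)), 2):
        mult = 1 if a == b else 2
        pairs[(cats[a], cats[b])] = n_e * mult * freq[a] * freq[b]
    trips = {}
    for combo in combinations_with_replacement(range(len(cats)), 3):
        counts = {c: combo.count(c) for c in set(combo)}
        mult = factorial(3)
        for c in counts.values():
            mult //= factorial(c)
        p = np.prod([freq[c] for c in combo])
        trips[tuple(cats[c] for c in combo)] = n_t * mult * float(p)
    return pairs, trips


def association_scores(
    tess: PeriodicTessellation,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Observed/expected adjacency scores with permutation confidence bands.

    Expected counts are means over ``n_permutations`` seeded random label
    permutations on the fixed mesh.  Classes never realised in any
    permutation get score NaN (undefined), not infinity.  Returns a tidy
    DataFrame: kind (pair|triplet), combo, observed, expected, score,
    ci_low, ci_high (permutation band on the score scale).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != tess.n_points:
        raise ValueError("labels do not cover tessellation points")
    lab, cats = _encode(labels)
    k = len(cats)
    rng = np.random.default_rng(seed)
    edges, tris = tess.edge_pairs, tess.triangles

    obs_p = np.bincount(_pair_codes(lab, edges, k), minlength=k * k)
    obs_t = np.bincount(_triplet_codes(lab, tris, k), minlength=k**3)
    perm_p = np.zeros((n_permutations, k * k))
    perm_t = np.zeros((n_permutations, k**3))
    for it in range(n_permutations):
        pl = rng.permutation(lab)
        perm_p[it] = np.bincount(_pair_codes(pl, edges, k), minlength=k * k)
        perm_t[it] = np.bincount(_triplet_codes(pl, tris, k), minlength=k**3)

    alpha = (1.0 - ci) / 2.0
    rows = []
    for kind, obs, perm, codes in (
        ("pair", obs_p, perm_p, [(a, b) for a, b in combinations_with_replacement(range(k), 2)]),
        ("triplet", obs_t, perm_t, [c for c in combinations_with_replacement(range(k), 3)]),
    ):
        for combo in codes:
            if kind == "pair":
                code = combo[0] * k + combo[1]
            else:
                code = (combo[0] * k + combo[1]) * k + combo[2]
            e = perm[:, code].mean()
            o = float(obs[code])
            if e > 0:
                score = o / e
                lo, hi = np.quantile(perm[:, code] / e, [alpha, 1.0 - alpha])
            else:
                score, lo, hi = np.nan, np.nan, np.nan
            rows.append(
                {
                    "kind": kind,
                    "combo": "-".join(cats[c] for c in combo),
                    "observed": o,
                    "expected": float(e),
                    "score": score,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
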