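"""Independent oracles used by the test suite.

Each oracle re-derives an expected result through a different route than
the implementation it checks: the relaxed transport optimum through a
linear program, boolean retrieval through a brute-force document scan, the
relaxation drop order through a standalone policy simulator, and entity
tagging through exhaustive span matching.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy.optimize import linprog

from biomedqa.lexicon import cosine_similarity, tokenize_simple


def relaxed_wmd_lp(q_weights: dict[str, float], a_terms: list[str], embeddings) -> float:
    """Optimum of the one-constraint-relaxed transport problem, via an LP.

    maximize Σ_ij T_ij · cossim(v_i, v_j)
    s.t.     Σ_j T_ij = w_i / Σ w   (supply side only; demand constraint
                                     dropped), T ≥ 0.
    """
    q = list(q_weights)
    a = list(dict.fromkeys(a_terms))
    nq, na = len(q), len(a)
    sims = np.zeros((nq, na))
    for i, qi in enumerate(q):
        for j, aj in enumerate(a):
            sims[i, j] = cosine_similarity(embeddings.get(qi), embeddings.get(aj))
    w = np.array([q_weights[s] for s in q], dtype=float)
    d = w / w.sum()
    A_eq = np.zeros((nq, nq * na))
    for i in range(nq):
        A_eq[i, i * na : (i + 1) * na] = 1.0
    res = linprog(-sims.ravel(), A_eq=A_eq, b_eq=d, bounds=(0, None), method="highs")
    assert res.success
    return -res.fun


def full_wmd_lp(d: np.ndarray, d_prime: np.ndarray, cost: np.ndarray) -> tuple[float, np.ndarray]:
    """The full transportation problem (both marginal constraints)."""
    n, m = cost.shape
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        A_eq.append(row)
        b_eq.append(d[i])
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1.0
        A_eq.append(row)
        b_eq.append(d_prime[j])
    res = linprog(cost.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun, res.x.reshape(n, m)


def brute_force_boolean(docs, constructs) -> set[str]:
    """A document matches iff every OR-group has a disjunct present in its
    title+abstract, phrases as contiguous token runs."""
    out = set()
    for doc in docs:
        toks = tokenize_simple(doc.title + " " + doc.abstract)
        ok = True
        for st in constructs:
            if not st.disjuncts:
                continue
            hit = False
            for surface, _ in st.disjuncts:
                ptoks = surface.lower().split()
                n = len(ptoks)
                for i in range(len(toks) - n + 1):
                    if toks[i : i + n] == ptoks:
                        hit = True
                        break
                if hit:
                    break
            if not hit:
                ok = False
                break
        if ok:
            out.add(doc.id)
    return out


def simulate_drop_order(query) -> list[tuple[str, int]]:
    """Standalone simulator of the relaxation policy's complete drop
    sequence: verb groups first (regardless of weight), then unprotected
    multi-disjunct groups by ascending max weight, then unprotected
    singletons, then protected groups (multi before singleton); within a
    group the lowest-weight disjunct goes first, weight ties by original
    question order / lexicographic surface."""
    constructs = [
        {
            "disjuncts": sorted(c.disjuncts, key=lambda d: (-d[1], d[0])),
            "kind": c.kind,
            "protected": c.protected,
            "origin": c.origin,
        }
        for c in copy.deepcopy(query.constructs)
    ]
    order: list[tuple[str, int]] = []
    while any(c["disjuncts"] for c in constructs):
        cs = [c for c in constructs if c["disjuncts"]]
        pools = [
            [c for c in cs if c["kind"] == "verb"],
            [c for c in cs if c["kind"] != "verb" and not c["protected"] and len(c["disjuncts"]) > 1],
            [c for c in cs if c["kind"] != "verb" and not c["protected"] and len(c["disjuncts"]) == 1],
            [c for c in cs if c["kind"] != "verb" and c["protected"] and len(c["disjuncts"]) > 1],
            [c for c in cs if c["kind"] != "verb" and c["protected"] and len(c["disjuncts"]) == 1],
        ]
        target = None
        for pool in pools:
            if pool:
                target = min(pool, key=lambda c: (c["disjuncts"][0][1], c["origin"]))
                break
        surface, _ = target["disjuncts"].pop()
        order.append((surface, target["origin"]))
    return order


def brute_force_tagging(tokens: list[str], table: dict[str, str]) -> list[tuple[int, int, str]]:
    """Greedy longest-match over spans, re-derived from scratch."""
    keys = {tuple(k.split()): v for k, v in table.items()}
    max_n = max((len(k) for k in keys), default=0)
    out = []
    i = 0
    low = [t.lower() for t in tokens]
    while i < len(tokens):
        found = None
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            if tuple(low[i : i + n]) in keys:
                found = (i, i + n, keys[tuple(low[i : i + n])])
                break
        if found:
            out.append(found)
            i = found[1]
        else:
            i += 1
    return out
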