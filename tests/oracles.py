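"""Independent reference implementations used as test oracles.

Everything here counts with plain Python data structures (lists, sets,
fractions of explicit counts) so that it shares no code path with the
package's vectorised/bitmask implementations.
"""

from __future__ import annotations

from itertools import combinations


def brute_support(itemset, transactions) -> float:
    itemset = set(itemset)
    return sum(1 for t in transactions if itemset <= set(t)) / len(transactions)


def brute_rules(
    transactions,
    min_lift: float = 1.0,
    consequent_sizes=(1, 2, 3),
    max_rule_size: int = 4,
    antecedent_constraint=None,
    minsup: float = 0.0,
    minconf: float = 0.0,
):
    """Exhaustively enumerate all disjoint (X, Y) pairs and their metrics.

    Returns a list of ``(antecedent frozenset, consequent frozenset,
    support, confidence, lift)`` sorted by (lift desc, support desc,
    confidence desc, label).
    """
    tx = [set(t) for t in transactions]
    items = sorted(set().union(*tx) if tx else set())
    n = len(tx)
    out = []
    sizes = set(consequent_sizes)
    for zsize in range(2, max_rule_size + 1):
        for z in combinations(items, zsize):
            zset = set(z)
            nz = sum(1 for t in tx if zset <= t)
            for xsize in range(1, zsize):
                for x in combinations(z, xsize):
                    xset = frozenset(x)
                    yset = frozenset(zset - xset)
                    if len(yset) not in sizes:
                        continue
                    if antecedent_constraint is not None and xset != frozenset(
                        antecedent_constraint
                    ):
                        continue
                    nx = sum(1 for t in tx if xset <= t)
                    ny = sum(1 for t in tx if yset <= t)
                    if nx == 0 or ny == 0:
                        continue
                    s = nz / n
                    c = nz / nx
                    lf = c * n / ny
                    if s >= minsup and c >= minconf and lf > min_lift:
                        out.append((xset, yset, s, c, lf))

    def label(x, y):
        return " & ".join(sorted(x)) + " => " + " & ".join(sorted(y))

    out.sort(key=lambda r: (-r[4], -r[2], -r[3], label(r[0], r[1])))
    return out


def random_transactions(rng, n_items: int, n_tx: int, p: float = 0.35):
    """Random transaction list over items a, b, c, ... for oracle tests."""
    items = [chr(ord("a") + i) for i in range(n_items)]
    return [
        frozenset(i for i in items if rng.random() < p) for _ in range(n_tx)
    ]


def tabulate_category(persons, diagnoses, cmap, category, categorize_fn):
    """2x2 counts of (index-disorder carrier) x (ever diagnosed in
    ``category``), counting directly from the raw record lists."""
    carriers = set(
        diagnoses.loc[diagnoses["icd9_code"] == cmap.index_code, "person_id"]
    )
    cat_codes = {
        c
        for c in diagnoses["icd9_code"].unique()
        if category in categorize_fn(c, cmap)
    }
    with_cat = set(
        diagnoses.loc[diagnoses["icd9_code"].isin(cat_codes), "person_id"]
    )
    a = b = c_ = d = 0
    for pid in persons["person_id"]:
        case = pid in carriers
        expo = pid in with_cat
        if case and expo:
            a += 1
        elif case:
            c_ += 1
        elif expo:
            b += 1
        else:
            d += 1
    return a, b, c_, d
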