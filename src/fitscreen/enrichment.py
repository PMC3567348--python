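"""Hypergeometric over-representation analysis of gene sets.

Two usage modes, mirroring the two tools common in yeast screens:

* fixed-universe mode — the reference is the whole annotation universe
  (every annotated gene), as in genome-wide screens;
* custom-reference mode — the reference is a user-defined gene set
  (e.g. a 123-ORF stress-reporter library), so enrichment asks whether
  a category is over-represented among hits *within that library*.

p-values are raw upper-tail hypergeometric probabilities; no filtering
by multiple-testing correction is applied (a BH column is emitted for
information only), matching how such tables are conventionally reported
at a fixed p threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationDB", "read_gmt", "hypergeom_tail", "enrich"]

log = logging.getLogger(__name__)

NAMESPACES = ("GO-MF", "GO-BP", "GO-CC", "MIPS", "other")


@dataclass
class AnnotationDB:
    """Gene-set annotation: categories plus the annotated universe.

    ``categories`` maps category id to ``(namespace, name, members)``;
    the universe is the union of all members unless given explicitly.
    """

    categories: dict
    universe: frozenset = field(default=None)

    def __post_init__(self) -> None:
        members = set()
        for cid, (ns, name, genes) in self.categories.items():
            if len(genes) < 1:
                raise ValueError(f"category {cid!r} is empty")
            members |= set(genes)
        if self.universe is None:
            self.universe = frozenset(members)
        else:
            self.universe = frozenset(self.universe)
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"category members outside universe: {sorted(stray)[:5]}..."
                )


def read_gmt(path) -> AnnotationDB:
    """Read a GMT file (``id<TAB>name<TAB>gene1<TAB>...`` per line).

    A namespace is parsed from the id prefix when it looks like
    ``GO:``/``MIPS``; otherwise ``other``.
    """
    cats = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, name, >=1 gene")
            cid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            ns = "GO-BP" if cid.startswith("GO:") else (
                "MIPS" if cid.upper().startswith("MIPS") else "other"
            )
            cats[cid] = (ns, name, frozenset(genes))
    return AnnotationDB(categories=cats)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes total, ``K`` in the category, ``n`` drawn (the test
    set), ``k`` observed in both.  Computed via the survival function in
    log space for numerical stability of small tails.
    """
    if not (0 <= k <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    if k > n:
        return 0.0
    # sum pmf from k to min(K, n) via log-pmf for stability
    upper = min(K, n)
    ks = np.arange(k, upper + 1)
    logs = stats.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logs.max()) * np.exp(logs - logs.max()).sum()))


def enrich(
    test_set,
    db: AnnotationDB,
    reference="universe",
    threshold: float = 0.01,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each category in a test set.

    Parameters
    ----------
    test_set
        The hit genes (e.g. sensitive strains, or activated reporter
        ORFs).  Genes outside the reference are dropped with a logged
        count.
    reference
        ``"universe"`` for fixed-universe mode, or an explicit gene set
        for custom-reference mode.
    threshold
        Raw-p cutoff for the returned rows (default 0.01).

    Returns rows ``category, namespace, name, p, q_bh, k, K, n, N,
    genes`` with ``p <= threshold`` sorted ascending by p (all rows if
    ``keep_all``).
    """
    test = set(test_set)
    if reference == "universe":
        ref = set(db.universe)
    else:
        ref = set(reference) & set(db.universe)
        dropped_ref = len(set(reference)) - len(ref)
        if dropped_ref:
            log.info("dropped %d reference genes absent from annotation", dropped_ref)
    dropped = len(test) - len(test & ref)
    if dropped:
        log.info("dropped %d test genes outside the reference", dropped)
    test &= ref
    if not test:
        log.warning("empty test set after restriction to reference")
        return pd.DataFrame(
            columns=["category", "namespace", "name", "p", "q_bh",
                     "k", "K", "n", "N", "genes"]
        )
    N, n = len(ref), len(test)
    rows = []
    for cid, (ns, name, genes) in db.categories.items():
        cat_ref = set(genes) & ref
        if not cat_ref:
            continue
        observed = sorted(cat_ref & test)
        rows.append(
            {
                "category": cid,
                "namespace": ns,
                "name": name,
                "p": hypergeom_tail(len(observed), len(cat_ref), n, N),
                "k": len(observed),
                "K": len(cat_ref),
                "n": n,
                "N": N,
                "genes": " ".join(observed),
            }
        )
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out = out.sort_values(["p", "category"], kind="mergesort").reset_index(drop=True)
    if not keep_all:
        out = out[out["p"] <= threshold].reset_index(drop=True)
    return out[["category", "namespace", "name", "p", "q_bh", "k", "K", "n", "N", "genes"]]
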