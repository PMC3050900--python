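"""GO term enrichment of a gene set against a gene universe.

Per term the 2x2 overlap (k study genes with the term, n study genes, K
population genes with the term, N population genes) yields a log2 odds-style
enrichment ratio log2((k/n)/(K/N)) and a one-sided hypergeometric tail
p-value P(X >= k), adjusted across terms by Benjamini-Hochberg (default) or
Benjamini-Yekutieli. Term-to-parent edges, when supplied, are propagated as a
transitive closure so a gene annotated to a term also counts toward every
ancestor (standard ontology practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_CORRECTIONS = {"bh": "fdr_bh", "by": "fdr_by", "none": None}


@dataclass
class GOAnnotation:
    """gene -> set of term ids, with optional term -> parents edges."""

    gene_terms: dict[str, set[str]]
    term_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_frames(
        cls, associations: pd.DataFrame, parents: pd.DataFrame | None = None
    ) -> "GOAnnotation":
        """Build from a two-column (gene, term) table and an optional
        (term, parent) edge table."""
        gene_terms: dict[str, set[str]] = {}
        for g, t in zip(associations.iloc[:, 0], associations.iloc[:, 1]):
            gene_terms.setdefault(str(g), set()).add(str(t))
        term_parents: dict[str, tuple[str, ...]] = {}
        if parents is not None:
            tmp: dict[str, list[str]] = {}
            for t, p in zip(parents.iloc[:, 0], parents.iloc[:, 1]):
                tmp.setdefault(str(t), []).append(str(p))
            term_parents = {t: tuple(sorted(ps)) for t, ps in tmp.items()}
        return cls(gene_terms, term_parents)

    def ancestors(self, term: str) -> set[str]:
        """All (transitive) parents of a term; cycles are tolerated."""
        seen: set[str] = set()
        stack = list(self.term_parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(self.term_parents.get(p, ()))
        return seen

    def propagated(self, gene: str) -> set[str]:
        """The gene's terms plus every ancestor of each."""
        direct = self.gene_terms.get(gene, set())
        out = set(direct)
        for t in direct:
            out |= self.ancestors(t)
        return out


def _terms_by_gene(annotation: GOAnnotation, genes, propagate: bool) -> dict[str, set[str]]:
    if propagate:
        return {g: annotation.propagated(g) for g in genes}
    return {g: set(annotation.gene_terms.get(g, set())) for g in genes}


def enrich(
    study_set,
    population,
    annotation: GOAnnotation,
    correction: str = "bh",
    propagate: bool = True,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Test every annotated term for over-representation in ``study_set``.

    Returns one row per term with counts (k, n, K, N), the log2 enrichment
    odds ratio (``-inf`` when k = 0), the raw hypergeometric tail p-value and
    the multiplicity-adjusted p-value, sorted by raw p. Terms absent from the
    population (K = 0) are skipped; a study gene carrying a term no
    population gene carries indicates an inconsistent annotation and raises.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    population = list(dict.fromkeys(population))
    study = list(dict.fromkeys(study_set))
    if not population:
        raise ValueError("population must be nonempty")
    missing = set(study) - set(population)
    if missing:
        raise ValueError(f"study genes not in population: {sorted(missing)[:5]}...")

    pop_terms = _terms_by_gene(annotation, population, propagate)
    study_terms = {g: pop_terms[g] for g in study}
    n, big_n = len(study), len(population)

    pop_count: dict[str, int] = {}
    for ts in pop_terms.values():
        for t in ts:
            pop_count[t] = pop_count.get(t, 0) + 1
    study_count: dict[str, int] = {}
    for ts in study_terms.values():
        for t in ts:
            study_count[t] = study_count.get(t, 0) + 1

    bad = set(study_count) - set(pop_count)
    if bad:
        raise ValueError(f"inconsistent annotation: study-only terms {sorted(bad)[:5]}")

    rows = []
    for term in sorted(pop_count):
        big_k = pop_count[term]
        k = study_count.get(term, 0)
        if big_k == 0:
            continue
        if k == 0:
            log_or = -np.inf
        else:
            log_or = float(np.log2((k / n) / (big_k / big_n)))
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "k": k,
                "n": n,
                "K": big_k,
                "N": big_n,
                "log_odds_ratio": log_or,
                "p_value": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        res["corrected_p"] = pd.Series(dtype=float)
        return res
    method = _CORRECTIONS[correction]
    if method is None:
        res["corrected_p"] = res["p_value"]
    else:
        res["corrected_p"] = multipletests(res["p_value"].to_numpy(), method=method)[1]
    return res.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def membrane_fraction(
    gene_set,
    annotation: GOAnnotation,
    membrane_terms,
    propagate: bool = True,
) -> float:
    """Fraction of genes annotated (after propagation) to any of the given
    membrane-related terms. Useful for set-level composition statements such
    as 'X% of the hits are membrane-related vs Y% genome-wide'."""
    membrane_terms = set(membrane_terms)
    if not membrane_terms:
        raise ValueError("membrane_terms must be nonempty")
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        return 0.0
    terms = _terms_by_gene(annotation, genes, propagate)
    hit = sum(1 for g in genes if terms[g] & membrane_terms)
    return hit / len(genes)
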