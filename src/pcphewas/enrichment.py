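"""Drug-target enrichment over the hierarchical ATC classification.

ATC codes form a five-level hierarchy (level 1, one letter, is the
anatomical group, e.g. "C" for the cardiovascular system; level 5, seven
characters, is an individual drug, e.g. "C07AB07" for bisoprolol).  Given a
gene -> ATC mapping, a node's gene set is the union of genes targeted by
drugs anywhere in its subtree.  For a phenotype, the genes significantly
associated at q <= 0.05 are tested for enrichment in each drug class with a
one-sided Fisher exact test on the 2x2 table (associated x in-class), and
the minimum p over each subtree is propagated to its root for display.

The universe defaults to all genes with an association result for the
phenotype; genes absent from the ATC mapping count as out-of-class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

#: Valid code lengths by ATC level.
_LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_LENGTH_LEVELS = {v: k for k, v in _LEVEL_LENGTHS.items()}
_CODE_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")

#: Minimum number of significant genes before the external ontology
#: enrichment adapter emits a gene list.
ONTOLOGY_MIN_GENES = 5


@dataclass
class ATCNode:
    code: str
    level: int
    parent: str | None
    gene_set: set[str] = field(default_factory=set)
    children: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Fisher exact enrichment of associated genes in one drug class."""

    code: str
    a: int   # associated and in class
    b: int   # associated, not in class
    c: int   # in class, not associated
    d: int   # neither
    p: float
    min_p_subtree: float | None = None

    def to_dict(self) -> dict:
        return {
            "code": self.code, "a": self.a, "b": self.b, "c": self.c,
            "d": self.d, "p": self.p, "min_p_subtree": self.min_p_subtree,
        }


def _code_prefixes(code: str) -> list[str]:
    """All hierarchy levels of a code: C07AB07 -> C, C07, C07A, C07AB, C07AB07."""
    return [code[:length] for length in sorted(_LEVEL_LENGTHS.values())
            if length <= len(code)]


def build_atc_tree(mapping: pd.DataFrame | str | Path) -> dict[str, ATCNode]:
    """Build the ATC tree from a gene -> code mapping.

    ``mapping`` is a DataFrame or TSV path with columns gene_id, atc_code
    (any level).  Nodes are created for every prefix level of every code and
    gene sets are propagated upward, so each node holds the union over its
    subtree.  Returns a dict keyed by code.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t")
    required = {"gene_id", "atc_code"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"mapping must have columns {sorted(required)}")

    tree: dict[str, ATCNode] = {}
    for i, row in enumerate(mapping.itertuples(index=False), start=1):
        code = str(row.atc_code).strip()
        if len(code) not in _LENGTH_LEVELS or not _CODE_RE.match(code):
            raise ValueError(f"row {i}: malformed ATC code {code!r}")
        gene = str(row.gene_id)
        prefixes = _code_prefixes(code)
        for depth, prefix in enumerate(prefixes):
            node = tree.get(prefix)
            if node is None:
                parent = prefixes[depth - 1] if depth else None
                node = ATCNode(prefix, _LENGTH_LEVELS[len(prefix)], parent)
                tree[prefix] = node
                if parent is not None and prefix not in tree[parent].children:
                    tree[parent].children.append(prefix)
            node.gene_set.add(gene)
    return tree


def fisher_enrichment(
    associated: set[str],
    node: ATCNode,
    universe: set[str],
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact test of associated genes against a drug class.

    The 2x2 table counts genes by (associated at q <= 0.05) x (targeted by
    the node's subtree); the one-sided p is the hypergeometric upper tail.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not associated <= universe:
        raise ValueError("associated genes must be a subset of the universe")
    in_class = node.gene_set & universe
    a = len(associated & in_class)
    b = len(associated - in_class)
    c = len(in_class - associated)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(node.code, a, b, c, d, float(p))


def subtree_min_p(
    tree: dict[str, ATCNode], results: dict[str, EnrichmentResult]
) -> dict[str, EnrichmentResult]:
    """Annotate each result with the minimum p over its subtree (post-order)."""
    def visit(code: str) -> float:
        node = tree[code]
        best = results[code].p
        for child in node.children:
            if child in results:
                best = min(best, visit(child))
        results[code].min_p_subtree = best
        return best

    for code, node in tree.items():
        if node.parent is None:
            visit(code)
    return results


def run_enrichment(
    associated: set[str],
    universe: set[str],
    mapping: pd.DataFrame | str | Path,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Enrichment across every ATC node, with subtree minimum-p annotation."""
    tree = build_atc_tree(mapping)
    results = {
        code: fisher_enrichment(associated, node, universe, alternative)
        for code, node in tree.items()
    }
    subtree_min_p(tree, results)
    rows = [results[code].to_dict() for code in sorted(results)]
    df = pd.DataFrame(
        rows, columns=["code", "a", "b", "c", "d", "p", "min_p_subtree"])
    if len(df):
        df["level"] = [tree[c].level for c in df["code"]]
    return df


def ontology_gene_list(associated: set[str],
                       min_genes: int = ONTOLOGY_MIN_GENES) -> list[str]:
    """Gene list for external ontology enrichment (KEGG/GO/HPO adapters).

    Returns the sorted significant gene list only when at least
    ``min_genes`` genes are associated; otherwise an empty list.  No remote
    call is made here — downstream tooling consumes the list.
    """
    if len(associated) < min_genes:
        return []
    return sorted(associated)
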