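"""Ortholog-clade calling, score-threshold calibration and module evaluation.

The workflow mirrors how phylogeny-anchored marker genes are curated for
dissimilatory sulfur metabolism: bootstrap-labelled protein trees carrying
tip-level evidence (biochemically verified ingroup/outgroup references, gene
neighbourhood tags, catalytic-residue/domain tags) are scanned for
monophyletic clades of functional orthologs; labelled bit-score distributions
are turned into per-model gathering thresholds by ROC analysis; genome hits
are assigned to their best-scoring passing model; model sets are benchmarked
by precision/recall/specificity/F-score; and pathway-module presence is
decided from a logic expression over annotated genes.

A clade is called when all three criteria hold:

1. bootstrap support strictly greater than a cut-off (default 70);
2. at least one verified ingroup member and no verified outgroup member;
3. consistent context: at least ``min_context_fraction`` of the
   neighbourhood-tagged members share a neighbourhood label with the verified
   ingroup member(s), and no member carries trait labels disjoint from the
   ingroup trait set.

Nested passing nodes collapse to the most inclusive one, so every reported
clade is maximal and clades are pairwise disjoint.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

TIP_STATUSES = ("ingroup_verified", "outgroup_verified", "uncharacterized")


@dataclass(frozen=True)
class TipEvidence:
    """Curated evidence attached to one tree tip."""

    status: str
    neighbourhood_labels: frozenset[str] = frozenset()
    trait_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in TIP_STATUSES:
            raise ValueError(f"status must be one of {TIP_STATUSES}")


class AnnotatedTree:
    """A rooted tree with bootstrap supports on internal nodes.

    Thin wrapper around :class:`dendropy.Tree`; internal-node newick labels
    are interpreted as plain-number bootstrap supports in [0, 100].  Nodes
    without a numeric label have ``support = None`` and are never called as
    clades.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip identifiers: {', '.join(dupes)}")
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd.support = None
                continue
            try:
                nd.support = float(nd.label) if nd.label is not None else None
            except (TypeError, ValueError):
                nd.support = None
            if nd.support is not None and not 0.0 <= nd.support <= 100.0:
                raise ValueError(f"bootstrap support {nd.support} outside [0, 100]")

    @classmethod
    def from_newick(cls, newick: str) -> "AnnotatedTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "AnnotatedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tips(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def internal_clades(self):
        """Yield (node, member tip set, support) for each internal node."""
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            members = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            yield nd, members, nd.support

    def to_newick(self) -> str:
        """Deterministic newick string with supports as internal labels."""

        def fmt(x: float) -> str:
            return f"{x:g}"

        def render(nd) -> str:
            if nd.is_leaf():
                s = nd.taxon.label
            else:
                s = "(" + ",".join(render(c) for c in nd.child_nodes()) + ")"
                if nd.support is not None:
                    s += fmt(nd.support)
            if nd.edge.length is not None:
                s += ":" + fmt(nd.edge.length)
            return s

        return render(self._tree.seed_node) + ";"


@dataclass(frozen=True)
class OrthologClade:
    """A called clade of functional orthologs."""

    members: frozenset[str]
    support: float
    n_ingroup: int
    n_outgroup: int
    n_uncharacterized: int
    ingroup_neighbourhood: frozenset[str]
    ingroup_traits: frozenset[str]


def _clade_passes(members: frozenset[str], support: float | None,
                  evidence: Mapping[str, TipEvidence], min_support: float,
                  min_context_fraction: float) -> bool:
    if support is None or not support > min_support:
        return False
    ev = [evidence[t] for t in members]
    ingroup = [e for e in ev if e.status == "ingroup_verified"]
    if not ingroup or any(e.status == "outgroup_verified" for e in ev):
        return False
    # Criterion 3: neighbourhood consistency among tagged members ...
    ingroup_nbr = frozenset().union(*(e.neighbourhood_labels for e in ingroup))
    if ingroup_nbr:
        tagged = [e for e in ev if e.neighbourhood_labels]
        sharing = sum(1 for e in tagged if e.neighbourhood_labels & ingroup_nbr)
        if tagged and sharing / len(tagged) < min_context_fraction:
            return False
    # ... and no trait label set disjoint from the ingroup traits.
    ingroup_traits = frozenset().union(*(e.trait_labels for e in ingroup))
    if ingroup_traits:
        for e in ev:
            if e.trait_labels and not (e.trait_labels & ingroup_traits):
                return False
    return True


def find_ortholog_clades(tree: AnnotatedTree,
                         evidence: Mapping[str, TipEvidence],
                         min_support: float = 70.0,
                         min_context_fraction: float = 0.8,
                         ) -> list[OrthologClade]:
    """Call maximal ortholog clades satisfying the three criteria.

    Returns pairwise-disjoint clades sorted by size (largest first) and then
    by smallest member identifier; polyphyletic ingroups yield several clades.
    """
    tips = set(tree.tips())
    missing = sorted(tips - set(evidence))
    if missing:
        raise ValueError(f"tips without evidence: {', '.join(missing)}")
    accepted: list[tuple[frozenset[str], float]] = []
    for _, members, support in tree.internal_clades():  # preorder: parents first
        if any(members <= acc for acc, _ in accepted):
            continue  # nested inside an already-called clade
        if _clade_passes(members, support, evidence, min_support,
                         min_context_fraction):
            accepted.append((members, support))
    clades = []
    for members, support in accepted:
        ev = [evidence[t] for t in members]
        ingroup = [e for e in ev if e.status == "ingroup_verified"]
        clades.append(OrthologClade(
            members=members, support=support,
            n_ingroup=len(ingroup),
            n_outgroup=0,
            n_uncharacterized=sum(1 for e in ev if e.status == "uncharacterized"),
            ingroup_neighbourhood=frozenset().union(
                *(e.neighbourhood_labels for e in ingroup)),
            ingroup_traits=frozenset().union(*(e.trait_labels for e in ingroup)),
        ))
    return sorted(clades, key=lambda c: (-len(c.members), min(c.members)))


# ---------------------------------------------------------------------------
# Score calibration and hit assignment


@dataclass(frozen=True)
class ScoreSet:
    """Labelled per-sequence bit scores for one model."""

    ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray  # bool: True = positive

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class ModelThreshold:
    """ROC-calibrated gathering threshold for one model."""

    model_id: str
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def calibrate_threshold(scores: ScoreSet, model_id: str = "model") -> ModelThreshold:
    """Choose the bit-score cut-off maximising Youden's J = sens + spec − 1.

    Candidate cut-points are the midpoints between adjacent distinct scores
    plus one point below the minimum and one above the maximum; a hit passes
    when its score is >= the threshold.  Ties in J resolve to the highest
    threshold (favouring specificity).  Inseparable inputs (all scores equal)
    yield the degenerate J = 0 operating point rather than an error.
    """
    pos = scores.scores[scores.labels.astype(bool)]
    neg = scores.scores[~scores.labels.astype(bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("calibration requires at least one positive and one negative")
    distinct = np.unique(scores.scores)
    candidates = [distinct[0] - 1.0, distinct[-1] + 1.0]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    best = None
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (j, t)  # ties toward the higher threshold
        if best is None or key > (best[0], best[1]):
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return ModelThreshold(model_id=model_id, threshold=float(t),
                          sensitivity=sens, specificity=spec)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Best-model assignment per gene of one genome."""

    genome_id: str
    hits: Mapping[str, tuple[str, float]]  # gene -> (model, score)

    def genes_with_model(self, model_id: str) -> set[str]:
        return {g for g, (m, _) in self.hits.items() if m == model_id}

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.hits)


def assign_hits(gene_scores: Mapping[str, Mapping[str, float]],
                thresholds: Mapping[str, "ModelThreshold | float"],
                genome_id: str = "genome") -> GenomeAnnotation:
    """Assign each gene to the highest-scoring model above its threshold.

    Genes with no model at or above its gathering threshold stay unannotated;
    score ties break deterministically toward the lexicographically smaller
    model identifier.
    """

    def cutoff(model: str) -> float:
        t = thresholds[model]
        return t.threshold if isinstance(t, ModelThreshold) else float(t)

    hits: dict[str, tuple[str, float]] = {}
    for gene in sorted(gene_scores):
        passing = [(model, float(s)) for model, s in gene_scores[gene].items()
                   if model in thresholds and math.isfinite(s) and s >= cutoff(model)]
        if not passing:
            continue
        best_score = max(s for _, s in passing)
        best_model = min(m for m, s in passing if s == best_score)
        hits[gene] = (best_model, best_score)
    return GenomeAnnotation(genome_id=genome_id, hits=hits)


# ---------------------------------------------------------------------------
# Benchmarking


@dataclass(frozen=True)
class BenchmarkReport:
    """Confusion-matrix metrics of one model set on labelled data."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    #: sensitivity is a synonym for recall
    sensitivity = recall

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def benchmark(predictions: Mapping[str, bool],
              truth: Mapping[str, bool]) -> BenchmarkReport:
    """Score binary predictions against truth labels over aligned identifiers.

    F = 2·(precision·recall)/(precision+recall), with F = 0 when the
    denominator vanishes.  A positive with no prediction entry counts as a
    false negative; a negative predicted positive counts as a false positive.
    """
    if not truth:
        raise ValueError("empty benchmark input")
    extra = set(predictions) - set(truth)
    if extra:
        raise ValueError(f"predictions for unknown identifiers: {sorted(extra)}")
    tp = fp = fn = tn = 0
    for ident, is_true in truth.items():
        pred = bool(predictions.get(ident, False))
        if pred and is_true:
            tp += 1
        elif pred and not is_true:
            fp += 1
        elif not pred and is_true:
            fn += 1
        else:
            tn += 1
    return BenchmarkReport(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Metabolic-module completeness

_TOKEN_RE = re.compile(r"\s+|[(),+-]|[A-Za-z0-9_.]+")


def _tokenize(expr: str):
    pos = 0
    for m in _TOKEN_RE.finditer(expr):
        if m.start() != pos:
            raise ValueError(f"module expression: unexpected character "
                             f"{expr[pos]!r} at position {pos}")
        pos = m.end()
        text = m.group()
        if text.isspace():
            yield ("SP", text, m.start())
        elif text in "(),+-":
            yield (text, text, m.start())
        else:
            yield ("ID", text, m.start())
    if pos != len(expr):
        raise ValueError(f"module expression: unexpected character "
                         f"{expr[pos]!r} at position {pos}")


class _Parser:
    """Recursive-descent parser for module logic expressions.

    Grammar (KEGG-module style): space = AND between steps, comma = OR,
    ``+`` = required complex component (AND), ``-`` = optional component
    (always satisfied), parentheses group.
    """

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = list(_tokenize(expr))
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else ("EOF", "", len(self.expr))

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse_top(self) -> list:
        steps = self.parse_steps()
        kind, _, pos = self.peek()
        if kind != "EOF":
            raise ValueError(f"module expression: unexpected token at position {pos}")
        return steps

    def parse_steps(self) -> list:
        steps = [self.parse_step()]
        while self.peek()[0] == "SP":
            self.take()
            if self.peek()[0] in ("EOF", ")", ","):
                break
            steps.append(self.parse_step())
        return steps

    def parse_step(self):
        node = self.parse_unit()
        parts = [node]
        while self.peek()[0] in ("+", "-"):
            op, _, _ = self.take()
            unit = self.parse_unit()
            parts.append(("optional", unit) if op == "-" else unit)
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_unit(self):
        kind, text, pos = self.peek()
        if kind == "ID":
            self.take()
            return ("id", text)
        if kind == "(":
            self.take()
            node = self.parse_alt()
            kind, _, pos = self.peek()
            if kind != ")":
                raise ValueError(f"module expression: expected ')' at position {pos}")
            self.take()
            return node
        raise ValueError(f"module expression: unexpected token at position {pos}")

    def parse_alt(self):
        branches = [self._branch()]
        while self.peek()[0] == ",":
            self.take()
            branches.append(self._branch())
        return branches[0] if len(branches) == 1 else ("or", branches)

    def _branch(self):
        steps = self.parse_steps()
        return steps[0] if len(steps) == 1 else ("and", steps)


def parse_module_expression(expr: str) -> list:
    """Parse a module logic expression into its list of top-level steps."""
    expr = expr.strip()
    if not expr:
        raise ValueError("empty module expression")
    return _Parser(expr).parse_top()


def _eval_node(node, genes: set[str]) -> bool:
    kind = node[0]
    if kind == "id":
        return node[1] in genes
    if kind == "and":
        return all(_eval_node(n, genes) for n in node[1])
    if kind == "or":
        return any(_eval_node(n, genes) for n in node[1])
    if kind == "optional":
        return True
    raise AssertionError(f"unknown node {kind}")


@dataclass(frozen=True)
class ModuleDefinition:
    """A pathway module: logic expression, diagnostic genes, threshold."""

    module_id: str
    expression: str
    diagnostic: frozenset[str]
    completeness_threshold: float = 0.70

    def __post_init__(self) -> None:
        if not self.diagnostic:
            raise ValueError(f"{self.module_id}: diagnostic gene set is empty")
        parse_module_expression(self.expression)  # validate eagerly


@dataclass(frozen=True)
class ModuleResult:
    module_id: str
    present: bool
    completeness: float
    steps_satisfied: int
    n_steps: int
    diagnostic_present: bool


def evaluate_module(annotation: "GenomeAnnotation | Iterable[str]",
                    module: ModuleDefinition,
                    diagnostic_rule: str = "all") -> ModuleResult:
    """Evaluate module presence for an annotated genome.

    Completeness is the fraction of satisfied top-level steps of the logic
    expression.  The module is present iff the diagnostic genes are detected
    (all of them by default; ``diagnostic_rule="any"`` relaxes this) AND
    completeness is strictly greater than the threshold.
    """
    if isinstance(annotation, GenomeAnnotation):
        genes = annotation.annotated_genes
    else:
        genes = set(annotation)
    steps = parse_module_expression(module.expression)
    satisfied = sum(1 for s in steps if _eval_node(s, genes))
    completeness = satisfied / len(steps)
    if diagnostic_rule == "all":
        diag = all(d in genes for d in module.diagnostic)
    elif diagnostic_rule == "any":
        diag = any(d in genes for d in module.diagnostic)
    else:
        raise ValueError("diagnostic_rule must be 'all' or 'any'")
    present = diag and completeness > module.completeness_threshold
    return ModuleResult(module_id=module.module_id, present=present,
                        completeness=completeness, steps_satisfied=satisfied,
                        n_steps=len(steps), diagnostic_present=diag)
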