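"""Domain types and readers/writers for disease–gene–drug connectivity data.

The toolkit revolves around a handful of small containers:

* :class:`WeightedNetwork` — an undirected, confidence-weighted
  protein–protein interaction (PPI) graph (a thin wrapper over
  :class:`networkx.Graph`);
* :class:`Corpus` / :class:`DocRecord` — term-annotated abstracts, the
  substrate of the literature-enrichment statistic;
* :class:`EvidenceRecord` / :class:`DirectionalityAnnotation` —
  per-abstract and aggregated drug→protein direction evidence;
* :class:`ExpressionProfile` — per-gene over/under/unchanged status;
* result records (:class:`RankedProtein`, :class:`DrugEnrichment`,
  :class:`DrugEffectAssessment`, :class:`ConfusionMetrics`).

All file formats are plain text: TSV edge lists or SIF for networks,
JSONL for corpora, TSV for evidence/expression/result tables, GraphML or
SIF for exported drug-target subnetworks. Confidences must lie in (0, 1];
violating inputs are rejected, never clamped.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

# direction codes <-> curation categories
CATEGORIES = ("activation", "inhibition", "indirect", "ambiguous", "unknown")
CATEGORY_TO_DIRECTION = {
    "activation": 1,
    "inhibition": -1,
    "indirect": 0,
    "ambiguous": 0,
    "unknown": 0,
}
#: accepted spellings in evidence files, mapped to direction codes
DIRECTION_WORDS = {
    "activation": 1,
    "up": 1,
    "up-regulated": 1,
    "upregulated": 1,
    "inhibition": -1,
    "down": -1,
    "down-regulated": -1,
    "downregulated": -1,
    "indirect": 0,
    "ambiguous": 0,
    "unknown": 0,
}
DIRECTION_TO_CATEGORY = {1: "activation", -1: "inhibition", 0: "unknown"}

STATUSES = ("over", "under", "unchanged")

EFFECTS = ("therapeutic", "toxic", "neutral", "ambiguous")

DIRECTIONALITY_LABELS = (
    "only-up",
    "only-down",
    "primarily-up",
    "primarily-down",
    "ambiguous",
)


def _check_protein_id(pid: str) -> str:
    if not isinstance(pid, str) or not pid:
        raise ValidationError(f"protein id must be a non-empty string, got {pid!r}")
    return pid


class WeightedNetwork:
    """Undirected confidence-weighted PPI graph.

    Edges are stored once per unordered pair with a ``conf`` attribute in
    (0, 1]. Self-loops are rejected. Adding an existing edge keeps the
    maximum confidence seen for the pair.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph() if graph is None else graph

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedNetwork":
        net = cls()
        for p, q, conf in edges:
            net.add_edge(p, q, conf)
        return net

    def add_node(self, p: str) -> None:
        self._g.add_node(_check_protein_id(p))

    def add_edge(self, p: str, q: str, conf: float) -> None:
        _check_protein_id(p)
        _check_protein_id(q)
        if p == q:
            raise ValidationError(f"self-loop on {p!r} is not allowed")
        conf = float(conf)
        if not (0.0 < conf <= 1.0):
            raise ValidationError(
                f"confidence for ({p}, {q}) must be in (0, 1], got {conf}"
            )
        if self._g.has_edge(p, q):
            conf = max(conf, self._g[p][q]["conf"])
        self._g.add_edge(p, q, conf=conf)

    # -- queries ------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """Underlying :class:`networkx.Graph` (edge attribute ``conf``)."""
        return self._g

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(p, q, d["conf"]) for p, q, d in self._g.edges(data=True)]

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, p: str) -> int:
        return self._g.degree(p)

    def neighbors(self, p: str) -> list[str]:
        return list(self._g.neighbors(p))

    def conf(self, p: str, q: str) -> float:
        return self._g[p][q]["conf"]

    def subgraph(self, nodes: Iterable[str]) -> "WeightedNetwork":
        return WeightedNetwork(self._g.subgraph(nodes).copy())

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self._g.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        mine = {frozenset((p, q)): c for p, q, c in self.edges()}
        theirs = {frozenset((p, q)): c for p, q, c in other.edges()}
        if mine.keys() != theirs.keys():
            return False
        return all(math.isclose(mine[k], theirs[k], rel_tol=1e-12) for k in mine)

    def __repr__(self) -> str:
        return (
            f"WeightedNetwork({self._g.number_of_nodes()} nodes, "
            f"{self._g.number_of_edges()} edges)"
        )


@dataclass(frozen=True)
class SeedList:
    """Disease seed genes: the starting set for subnetwork expansion."""

    disease_name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("seed list must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("seed list contains duplicate ids")
        for g in self.genes:
            _check_protein_id(g)


@dataclass(frozen=True)
class DocRecord:
    """One term-annotated abstract (PMID-like id plus term sets)."""

    doc_id: str
    drug_terms: frozenset[str] = frozenset()
    protein_terms: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")
        object.__setattr__(self, "drug_terms", frozenset(self.drug_terms))
        object.__setattr__(self, "protein_terms", frozenset(self.protein_terms))


@dataclass
class Corpus:
    """A labelled collection of :class:`DocRecord` (retrieved or background)."""

    records: list[DocRecord]
    label: str = "retrieved"

    def __post_init__(self):
        if self.label not in ("retrieved", "background"):
            raise ValidationError(
                f"corpus label must be 'retrieved' or 'background', got {self.label!r}"
            )
        if not self.records:
            raise ValidationError("corpus must contain at least one record")
        ids = [r.doc_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate doc_id in corpus")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DocRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class EvidenceRecord:
    """One abstract's evidence for a drug→protein direction.

    ``direction`` is +1 for activation/up-regulation, −1 for
    inhibition/down-regulation and 0 for indirect/ambiguous/unknown;
    it must agree with ``category``.
    """

    drug: str
    protein: str
    doc_id: str
    direction: int
    category: str = ""

    def __post_init__(self):
        if not self.drug or not self.protein or not self.doc_id:
            raise ValidationError("drug, protein and doc_id must be non-empty")
        if self.direction not in (-1, 0, 1):
            raise ValidationError(f"direction must be -1, 0 or 1, got {self.direction}")
        if not self.category:
            object.__setattr__(
                self, "category", DIRECTION_TO_CATEGORY[self.direction]
            )
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if CATEGORY_TO_DIRECTION[self.category] != self.direction:
            raise ValidationError(
                f"category {self.category!r} inconsistent with direction {self.direction}"
            )


@dataclass(frozen=True)
class DirectionalityAnnotation:
    """Aggregated direction for one (drug, protein) pair with vote counts."""

    drug: str
    protein: str
    direction: int
    n_up: int
    n_down: int
    n_other: int
    label: str

    def __post_init__(self):
        if self.direction not in (-1, 0, 1):
            raise ValidationError(f"direction must be -1, 0 or 1, got {self.direction}")
        if min(self.n_up, self.n_down, self.n_other) < 0:
            raise ValidationError("vote counts must be non-negative")
        if self.label not in DIRECTIONALITY_LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def n_records(self) -> int:
        return self.n_up + self.n_down + self.n_other


class ExpressionProfile:
    """Per-gene differential-expression status.

    Genes not present in the table are reported as ``"unchanged"``, so a
    profile may list only the differential genes.
    """

    def __init__(self, statuses: Mapping[str, str]):
        for gene, status in statuses.items():
            _check_protein_id(gene)
            if status not in STATUSES:
                raise ValidationError(
                    f"status for {gene!r} must be one of {STATUSES}, got {status!r}"
                )
        self._m = dict(statuses)

    @classmethod
    def from_logfc(cls, logfc: Mapping[str, float], threshold: float) -> "ExpressionProfile":
        """Threshold a log fold-change table symmetrically into statuses."""
        if threshold <= 0:
            raise ValidationError("logFC threshold must be positive")
        m = {}
        for gene, v in logfc.items():
            v = float(v)
            if v >= threshold:
                m[gene] = "over"
            elif v <= -threshold:
                m[gene] = "under"
            else:
                m[gene] = "unchanged"
        return cls(m)

    def status(self, gene: str) -> str:
        return self._m.get(gene, "unchanged")

    __getitem__ = status

    @property
    def genes(self) -> list[str]:
        return list(self._m)

    def items(self):
        return self._m.items()

    def __len__(self) -> int:
        return len(self._m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionProfile):
            return NotImplemented
        return self._m == other._m


@dataclass(frozen=True)
class RankedProtein:
    """A protein with its network relevance score r_p."""

    protein_id: str
    r_p: float
    is_seed: bool = False

    def __post_init__(self):
        if not math.isfinite(self.r_p):
            raise ValidationError(f"r_p for {self.protein_id!r} must be finite")


@dataclass(frozen=True)
class DrugEnrichment:
    """Enrichment of one drug term in the retrieved vs background corpus.

    ``delta`` is the Welch-type statistic on resampled document
    frequencies; ``p_value`` its two-sided t-test p; ``rel_freq`` the
    term's document frequency over the whole retrieved corpus.
    """

    drug: str
    delta: float
    p_value: float
    mean_df_net: float
    mean_df_bg: float
    var_df_net: float
    var_df_bg: float
    n_net: int
    n_bg: int
    rel_freq: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value must be in [0, 1], got {self.p_value}")
        if not (0.0 <= self.rel_freq <= 1.0):
            raise ValidationError(f"rel_freq must be in [0, 1], got {self.rel_freq}")
        if self.var_df_net < 0 or self.var_df_bg < 0:
            raise ValidationError("variances must be non-negative")

    @property
    def association(self) -> float:
        """−log10(p), a convenience association score (artifact definition)."""
        return float("inf") if self.p_value == 0 else -math.log10(self.p_value)


@dataclass(frozen=True)
class PairEffect:
    """Effect of one drug on one annotated partner protein."""

    protein: str
    r_p: float
    direction: int
    status: str
    effect: str


@dataclass
class DrugEffectAssessment:
    """Per-pair effect labels plus the r_p-weighted net efficacy score.

    ``net_score`` is the sum of r_p over therapeutic pairs minus the sum
    over toxic pairs; ``overall`` thresholds it at ±tau.
    """

    drug: str
    pairs: list[PairEffect]
    counts: dict[str, int]
    net_score: float
    overall: str
    tau: float = 0.0

    def __post_init__(self):
        if sum(self.counts.values()) != len(self.pairs):
            raise ValidationError("effect counts must sum to the number of pairs")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary-classification metrics (fractions in [0, 1])."""

    sensitivity: float
    specificity: float
    ppv: float
    f_score: float
    acc: float

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "ppv", "f_score", "acc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#'."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield i, line


def read_network(path, min_conf: float = 0.0) -> WeightedNetwork:
    """Read a weighted edge list (TSV ``a b conf`` or SIF ``a conf b``).

    Duplicate undirected pairs keep the maximum confidence; self-loops
    are dropped with a warning; edges with ``conf < min_conf`` are
    excluded. A header row is skipped if its confidence field is not
    numeric.
    """
    path = Path(path)
    sif = path.suffix.lower() == ".sif"
    net = WeightedNetwork()
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3:
            raise ParseError(
                f"expected 3 columns, got {len(fields)}", path=path, line=lineno
            )
        if sif:
            a, conf_s, b = fields
        else:
            a, b, conf_s = fields
        try:
            conf = float(conf_s)
        except ValueError:
            if first:  # header row
                first = False
                continue
            raise ParseError(
                f"confidence {conf_s!r} is not a number", path=path, line=lineno
            ) from None
        first = False
        if not (0.0 < conf <= 1.0):
            raise ValidationError(
                f"{path}:{lineno}: confidence must be in (0, 1], got {conf}"
            )
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
            continue
        if conf < min_conf:
            continue
        net.add_edge(a, b, conf)
    return net


def write_network(net: WeightedNetwork, path) -> None:
    """Write a network as TSV (or SIF when the path ends in ``.sif``)."""
    path = Path(path)
    sif = path.suffix.lower() == ".sif"
    with open(path, "w", encoding="utf-8") as fh:
        if not sif:
            fh.write("protein_a\tprotein_b\tconfidence\n")
        for p, q, conf in sorted(net.edges()):
            if sif:
                fh.write(f"{p}\t{conf:.6g}\t{q}\n")
            else:
                fh.write(f"{p}\t{q}\t{conf:.6g}\n")


def read_seed_list(path, disease_name: str | None = None) -> SeedList:
    """Read a plain-text seed gene list (one id per line)."""
    path = Path(path)
    genes: list[str] = []
    for _, line in _data_lines(path):
        gene = line.split()[0]
        if gene not in genes:
            genes.append(gene)
    if not genes:
        raise ValidationError(f"{path}: seed list is empty")
    return SeedList(disease_name or path.stem, tuple(genes))


def read_corpus(path, label: str = "retrieved") -> Corpus:
    """Read a JSONL corpus: one object per line with ``doc_id``,
    ``drug_terms`` and ``protein_terms``."""
    records = []
    for lineno, line in _data_lines(path):
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON ({exc.msg})", path=path, line=lineno)
        if "doc_id" not in obj:
            raise ParseError("missing 'doc_id'", path=path, line=lineno)
        records.append(
            DocRecord(
                doc_id=str(obj["doc_id"]),
                drug_terms=frozenset(obj.get("drug_terms", ())),
                protein_terms=frozenset(obj.get("protein_terms", ())),
            )
        )
    return Corpus(records, label=label)


def write_corpus(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(
                json.dumps(
                    {
                        "doc_id": rec.doc_id,
                        "drug_terms": sorted(rec.drug_terms),
                        "protein_terms": sorted(rec.protein_terms),
                    }
                )
                + "\n"
            )


def _parse_direction(token: str, path, lineno: int) -> int:
    tok = token.strip().lower()
    if tok in ("-1", "0", "1", "+1"):
        return int(tok)
    if tok in DIRECTION_WORDS:
        return DIRECTION_WORDS[tok]
    raise ValidationError(
        f"{path}:{lineno}: unknown direction {token!r} "
        f"(expected -1/0/1 or one of {sorted(DIRECTION_WORDS)})"
    )


_EVIDENCE_HEADER = {"drug", "protein", "pmid", "doc_id", "direction", "category"}


def read_evidence(path) -> list[EvidenceRecord]:
    """Read per-abstract evidence: TSV with drug, protein, pmid, direction
    columns and an optional category column.

    Direction may be a code (−1/0/1) or a curation word (up, inhibition,
    ...). An empty file yields an empty list.
    """
    path = Path(path)
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if {f.strip().lower() for f in fields} & _EVIDENCE_HEADER and lineno == 1:
            continue  # header
        if len(fields) not in (4, 5):
            raise ParseError(
                f"expected 4 or 5 columns, got {len(fields)}", path=path, line=lineno
            )
        drug, protein, pmid, direction_s = fields[:4]
        direction = _parse_direction(direction_s, path, lineno)
        category = fields[4].strip().lower() if len(fields) == 5 else ""
        word = direction_s.strip().lower()
        if not category and word in CATEGORIES:
            category = word
        records.append(
            EvidenceRecord(
                drug=drug, protein=protein, doc_id=pmid,
                direction=direction, category=category,
            )
        )
    return records


def write_evidence(records: Sequence[EvidenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tprotein\tpmid\tdirection\tcategory\n")
        for r in records:
            fh.write(f"{r.drug}\t{r.protein}\t{r.doc_id}\t{r.direction}\t{r.category}\n")


def read_expression(path, logfc_threshold: float | None = None) -> ExpressionProfile:
    """Read an expression table: ``gene<TAB>status`` or ``gene<TAB>logFC``.

    A numeric second column requires ``logfc_threshold``; statuses must
    be over/under/unchanged.
    """
    path = Path(path)
    statuses: dict[str, str] = {}
    logfc: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 columns, got {len(fields)}", path=path, line=lineno
            )
        gene, val = fields
        if gene.lower() == "gene":
            continue  # header
        try:
            logfc[gene] = float(val)
        except ValueError:
            if val not in STATUSES:
                raise ValidationError(
                    f"{path}:{lineno}: status must be one of {STATUSES} "
                    f"or numeric logFC, got {val!r}"
                ) from None
            statuses[gene] = val
    if logfc and statuses:
        raise ValidationError(f"{path}: mixed status and logFC rows")
    if logfc:
        if logfc_threshold is None:
            raise ValidationError(
                f"{path}: numeric logFC column requires a threshold"
            )
        return ExpressionProfile.from_logfc(logfc, logfc_threshold)
    return ExpressionProfile(statuses)


def write_expression(profile: ExpressionProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tstatus\n")
        for gene, status in sorted(profile.items()):
            fh.write(f"{gene}\t{status}\n")


def write_ranked(ranked: Sequence[RankedProtein], path, metadata: Mapping | None = None) -> None:
    """Write a protein ranking; r_p at 2 decimals for display plus a
    full-precision column."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("protein\tr_p\tr_p_full\tis_seed\n")
        for r in ranked:
            fh.write(f"{r.protein_id}\t{r.r_p:.2f}\t{r.r_p!r}\t{int(r.is_seed)}\n")


def read_scores(path) -> dict[str, float]:
    """Read a protein→r_p map from a ranking TSV (full precision column
    when present, else the display column)."""
    scores: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "protein":
            continue
        if len(fields) < 2:
            raise ParseError("expected at least 2 columns", path=path, line=lineno)
        scores[fields[0]] = float(fields[2] if len(fields) >= 3 else fields[1])
    return scores


def write_enrichment(results: Sequence[DrugEnrichment], path, metadata: Mapping | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write(
            "drug\tdelta\tp_value\trel_freq\tassociation\t"
            "mean_df_net\tmean_df_bg\tvar_df_net\tvar_df_bg\tn_net\tn_bg\n"
        )
        for r in results:
            fh.write(
                f"{r.drug}\t{r.delta!r}\t{r.p_value!r}\t{r.rel_freq!r}\t"
                f"{r.association!r}\t{r.mean_df_net!r}\t{r.mean_df_bg!r}\t"
                f"{r.var_df_net!r}\t{r.var_df_bg!r}\t{r.n_net}\t{r.n_bg}\n"
            )


def write_annotations(annotations: Sequence[DirectionalityAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tprotein\tdirection\tn_up\tn_down\tn_other\tlabel\n")
        for a in annotations:
            fh.write(
                f"{a.drug}\t{a.protein}\t{a.direction}\t"
                f"{a.n_up}\t{a.n_down}\t{a.n_other}\t{a.label}\n"
            )


def read_annotations(path) -> list[DirectionalityAnnotation]:
    path = Path(path)
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "drug":
            continue
        if len(fields) != 7:
            raise ParseError("expected 7 columns", path=path, line=lineno)
        drug, protein, direction, n_up, n_down, n_other, label = fields
        out.append(
            DirectionalityAnnotation(
                drug=drug, protein=protein, direction=int(direction),
                n_up=int(n_up), n_down=int(n_down), n_other=int(n_other),
                label=label,
            )
        )
    return out


def assessment_to_dict(assessment: DrugEffectAssessment) -> dict:
    return {
        "drug": assessment.drug,
        "overall": assessment.overall,
        "net_score": assessment.net_score,
        "tau": assessment.tau,
        "counts": dict(assessment.counts),
        "pairs": [
            {
                "protein": p.protein,
                "r_p": p.r_p,
                "direction": p.direction,
                "status": p.status,
                "effect": p.effect,
            }
            for p in assessment.pairs
        ],
    }


def write_assessment(assessment: DrugEffectAssessment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(assessment_to_dict(assessment), fh, indent=2)
        fh.write("\n")


# node/edge display attributes for exported drug-target subnetworks
_STATUS_COLOR = {"over": "red", "under": "green", "unchanged": "grey"}
_DIRECTION_COLOR = {1: "red", -1: "green", 0: "grey"}
_DIRECTION_RELATION = {1: "activates", -1: "inhibits", 0: "unknown"}


def write_subnetwork(assessment: DrugEffectAssessment, path, format: str = "graphml") -> None:
    """Export a drug-target star subnetwork.

    The drug node carries ``shape=hexagon``; protein nodes carry their
    r_p (``size``) and expression status (``color``: over→red,
    under→green); edges carry the direction (activate→red,
    inhibit→green). GraphML preserves all attributes; SIF keeps only the
    relation word.
    """
    if format not in ("graphml", "sif"):
        raise ValidationError(f"unknown subnetwork format {format!r}")
    from .drug_effect import build_drug_subnetwork  # local import: avoids cycle

    g = build_drug_subnetwork(assessment)
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for _, protein, d in g.edges(data=True):
                fh.write(
                    f"{assessment.drug}\t{_DIRECTION_RELATION[d['direction']]}\t{protein}\n"
                )


def read_subnetwork(path) -> nx.Graph:
    """Read back a GraphML drug-target subnetwork."""
    return nx.read_graphml(path)
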