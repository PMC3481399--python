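"""End-to-end pipeline: network mining → literature mining → pair
selection → directionality → drug-effect assessment, with a checksum
manifest.

The pipeline is driven by a :class:`RunConfig` (usually loaded from a
YAML file). Stages whose inputs are not configured are skipped; every
written artifact is listed in ``manifest.json`` with its sha256, so a
rerun with the same config and seed is byte-identical (no timestamps
are embedded in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .directionality import aggregate_all
from .drug_effect import assess_drug
from .errors import DGConnectError, ValidationError
from .literature_mining import co_mention_counts, enrich_drugs, select_top_pairs
from .model_io import (
    read_corpus,
    read_evidence,
    read_expression,
    read_network,
    read_seed_list,
    write_annotations,
    write_assessment,
    write_enrichment,
    write_ranked,
    write_subnetwork,
)
from .network_mining import expand_subnetwork, rank_proteins

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters and I/O paths for one pipeline run."""

    # inputs (paths; optional stages may be None)
    network: str | None = None
    seeds: str | None = None
    retrieved: str | None = None
    background: str | None = None
    vocab: str | None = None
    evidence: str | None = None
    expression: str | None = None
    drugs: list[str] = field(default_factory=list)
    outdir: str = "dgconnect_out"
    # parameters (defaults follow the method's stated values)
    k: float = 2.0
    depth: int = 1
    min_conf: float = 0.0
    n_samples: int = 100
    sample_size: int | None = None
    method: str = "partition"
    alpha: float = 0.05
    tau: float = 0.0
    top_n: int = 500
    logfc_threshold: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if self.k <= 0:
            raise ValidationError("k must be positive")
        if not (0.0 <= self.min_conf <= 1.0):
            raise ValidationError("min_conf must be in [0, 1]")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.method not in ("partition", "bootstrap"):
            raise ValidationError(f"unknown method {self.method!r}")
        for name in ("network", "seeds", "retrieved", "background",
                     "vocab", "evidence", "expression"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Tag exceptions from a stage so failures are attributable."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, ValidationError):
                raise DGConnectError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run all configured stages; return {artifact name: path}.

    Requires at least the network-mining inputs (network + seeds).
    Literature mining runs when both corpora and a vocabulary are
    given; directionality when an evidence file is given; drug-effect
    assessment when both annotations and an expression profile are
    available.
    """
    config.validate()
    if config.network is None or config.seeds is None:
        raise ValidationError("pipeline requires network and seeds inputs")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    meta = {"version": __version__, "seed": config.seed, "k": config.k,
            "depth": config.depth, "min_conf": config.min_conf}

    with _stage("network-mining"):
        network = read_network(config.network, min_conf=config.min_conf)
        seeds = read_seed_list(config.seeds)
        sub = expand_subnetwork(seeds, network, depth=config.depth)
        ranked = rank_proteins(sub, k=config.k, seeds=seeds)
        path = outdir / "ranked.tsv"
        write_ranked(ranked, path, metadata=meta)
        artifacts["ranked"] = str(path)

    enriched = None
    retrieved = None
    if config.retrieved and config.background and config.vocab:
        with _stage("literature-mining"):
            retrieved = read_corpus(config.retrieved, label="retrieved")
            background = read_corpus(config.background, label="background")
            vocab = set(read_seed_list(config.vocab, "vocab").genes)
            enriched = enrich_drugs(
                retrieved, background, vocab,
                n_samples=config.n_samples, sample_size=config.sample_size,
                seed=config.seed, method=config.method,
            )
            path = outdir / "enrichment.tsv"
            write_enrichment(
                enriched, path,
                metadata={**meta, "n_samples": config.n_samples,
                          "method": config.method},
            )
            artifacts["enrichment"] = str(path)

    if enriched is not None and retrieved is not None:
        with _stage("pair-selection"):
            counts = co_mention_counts(retrieved)
            significant = [e for e in enriched if e.p_value < config.alpha]
            pairs = select_top_pairs(ranked, significant, counts, config.top_n)
            path = outdir / "pairs.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("drug\tprotein\n")
                for drug, protein in pairs:
                    fh.write(f"{drug}\t{protein}\n")
            artifacts["pairs"] = str(path)

    annotations = None
    if config.evidence:
        with _stage("directionality"):
            records = read_evidence(config.evidence)
            annotations = aggregate_all(records)
            path = outdir / "annotations.tsv"
            write_annotations(annotations, path)
            artifacts["annotations"] = str(path)

    if annotations and config.expression:
        with _stage("drug-effect"):
            profile = read_expression(
                config.expression, logfc_threshold=config.logfc_threshold
            )
            scores = {r.protein_id: r.r_p for r in ranked}
            drugs = config.drugs or sorted({a.drug for a in annotations})
            for drug in drugs:
                assessment = assess_drug(
                    drug, annotations, profile, scores, tau=config.tau
                )
                jpath = outdir / f"assessment_{drug}.json"
                gpath = outdir / f"subnetwork_{drug}.graphml"
                write_assessment(assessment, jpath)
                write_subnetwork(assessment, gpath, format="graphml")
                artifacts[f"assessment_{drug}"] = str(jpath)
                artifacts[f"subnetwork_{drug}"] = str(gpath)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "artifacts": {
            name: {"path": p, "sha256": _sha256(Path(p))}
            for name, p in artifacts.items()
        },
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = str(mpath)
    return artifacts
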