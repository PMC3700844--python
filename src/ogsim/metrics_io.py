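"""Memory accounting, compression metrics, and file output.

Memory is reported under a deterministic byte model rather than process
RSS, so numbers are reproducible across hardware: an explicit sequence of
length L is charged L bytes, an explicit pathway of n genes n**2 bytes, and
each stored operation record its payload (one byte for a point mutation,
one per inserted base, small fixed constants for deletions, crossovers and
binding-site events — see ``genotype_models.RECORD_PAYLOAD_BYTES``).  A
consequence worth stating: a million point-mutation records weigh exactly
as much as one explicit megabase sequence, which is why bounding the number
of explicit genotypes bounds the heap.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

from . import genotype_models as gm
from .operation_graph import OperationGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class HeapAccount:
    """Byte-model heap usage: explicit genotypes plus operation records."""

    explicit_genotype_bytes: int
    operation_bytes: int

    @property
    def total(self) -> int:
        return self.explicit_genotype_bytes + self.operation_bytes


def heap_account(og: OperationGraph) -> HeapAccount:
    explicit = sum(gm.footprint(og.nodes[i].label) for i in og.cached_set)
    return HeapAccount(explicit, og.operation_record_bytes)


def compression_metrics(cached_count: int, N: int) -> tuple[float, float]:
    """Compression ratio ``cached/N`` and space savings ``(1-ratio)*100`` (a
    percentage): k explicit genotypes standing in for N individuals."""
    if cached_count < 1:
        raise ValueError("cached_count must be >= 1")
    if cached_count > N:
        raise ValueError(f"cached_count {cached_count} exceeds population {N}")
    ratio = cached_count / N
    return ratio, (1.0 - ratio) * 100.0


def memory_ceiling_k(ceiling_mb: float, genotype_mb: float) -> int:
    """Cache budget that keeps explicit genotypes under ``ceiling_mb``:
    ``floor(ceiling / per-genotype size)``, at least 1.  For sequences the
    per-genotype size is roughly L/1e6 MB.  A genotype larger than the
    ceiling cannot be accommodated below one explicit copy; the budget
    degrades to 1 with a warning."""
    if ceiling_mb <= 0 or genotype_mb <= 0:
        raise ValueError("ceiling and per-genotype size must be positive")
    if genotype_mb > ceiling_mb:
        logger.warning(
            "one genotype (%.3g MB) exceeds the %.3g MB ceiling; k=1",
            genotype_mb, ceiling_mb)
        return 1
    return max(1, math.floor(ceiling_mb / genotype_mb))


# ---------------------------------------------------------------------------
# output


METRIC_COLUMNS = (
    "generation", "seconds_per_generation", "heap_bytes",
    "explicit_genotype_bytes", "operation_bytes", "cached_count",
    "node_count", "edge_count", "compression_ratio", "space_savings",
)


def check_writable(out_dir) -> Path:
    """Fail fast before a long run: create the output directory and prove it
    accepts writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    finally:
        if probe.exists():
            probe.unlink()
    return out


def write_metrics_csv(metrics: Iterable, path) -> int:
    """One CSV row per generation (comma separated, header, '.' decimal)."""
    rows = 0
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=METRIC_COLUMNS)
        writer.writeheader()
        for m in metrics:
            writer.writerow({k: getattr(m, k) for k in METRIC_COLUMNS})
            rows += 1
    return rows


def write_metrics_jsonl(metrics: Iterable, path) -> int:
    rows = 0
    with open(path, "w") as fh:
        for m in metrics:
            fh.write(json.dumps(asdict(m)) + "\n")
            rows += 1
    return rows


def emit(result, out_dir, sample_size: int = 20) -> dict[str, str]:
    """Write a run's outputs under ``out_dir``: ``metrics.csv`` and
    ``metrics.jsonl``; ``sample.fasta`` (sequence mode, record ids
    ``<individual>_node<og id>``) or ``pathway.edges.tsv`` (pathway mode,
    most frequent genotype); and a final ``og.dot`` snapshot.  Returns the
    paths written."""
    from .genotype_models import PathwayGenotype, SequenceGenotype

    out = check_writable(out_dir)
    paths: dict[str, str] = {}
    write_metrics_csv(result.metrics, out / "metrics.csv")
    paths["metrics_csv"] = str(out / "metrics.csv")
    write_metrics_jsonl(result.metrics, out / "metrics.jsonl")
    paths["metrics_jsonl"] = str(out / "metrics.jsonl")

    pop = result.population
    memo: dict = {}
    take = min(sample_size, len(pop))
    genos = [result.og.decompress(int(pop[i]), memo) for i in range(take)]
    if genos and isinstance(genos[0], SequenceGenotype):
        ids = [f"{i}_node{int(pop[i])}" for i in range(take)]
        gm.write_fasta(out / "sample.fasta", genos, ids)
        paths["sample_fasta"] = str(out / "sample.fasta")
    elif genos and isinstance(genos[0], PathwayGenotype):
        import numpy as np

        ids_, counts = np.unique(pop, return_counts=True)
        top = int(ids_[int(counts.argmax())])
        gm.write_edge_list(out / "pathway.edges.tsv", result.og.decompress(top, memo))
        paths["pathway_edges"] = str(out / "pathway.edges.tsv")
    result.og.write_dot(out / "og.dot")
    paths["og_dot"] = str(out / "og.dot")
    return paths
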