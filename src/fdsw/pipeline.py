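"""End-to-end search: filter on composition, align what survives.

The pipeline mirrors a two-sided producer/consumer design: the
composition filter selects candidate database sequences, which are
dispatched for alignment in batches so filtering and alignment could
overlap. Batching is a correctness-neutral contract here — results are
defined to be identical to the fully sequential execution, and tests
hold the pipeline to that.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .align import AlignmentParams, batch_scores
from .errors import ValidationError
from .filtration import FiltrationConfig, apply_fdfs, frequency_vector
from .matrices import load_substitution_matrix
from .seqdb import load_index, read_fasta, validate_residues

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchResult:
    query_id: str
    db_id: str
    length: int
    fd: int | None
    selected: bool
    score: int | None  # defined iff selected

    def __post_init__(self) -> None:
        if self.selected != (self.score is not None):
            raise ValidationError(
                "score must be defined exactly for selected sequences"
            )


@dataclass
class RunConfig:
    query_path: str
    index_path: str
    identity_threshold: float = 0.9
    matrix_source: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 2
    fd_definition: str = "max_signed_sums"
    workers: int = 1
    batch_size: int = 1000
    output_path: str | None = None
    emit_filtered: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.workers < 1:
            raise ValidationError(f"workers must be >= 1, got {self.workers}")


def run_search(config: RunConfig) -> list[SearchResult]:
    """Filter the indexed database against the query, align the survivors.

    Selected sequences are scored in batches of ``batch_size``; scored
    rows are sorted by score descending with ties broken by database id.
    Rows for filtered-out sequences (score NA) are appended, sorted by
    id, only when ``emit_filtered`` is set. If ``output_path`` is set
    the same rows are written as a TSV report.
    """
    t0 = time.monotonic()
    queries = read_fasta(config.query_path)
    if len(queries) != 1:
        raise ValidationError(
            f"expected exactly one query sequence, got {len(queries)}"
        )
    query = queries[0]
    db = load_index(config.index_path)
    validate_residues(query, db.alphabet)
    matrix = load_substitution_matrix(config.matrix_source)
    params = AlignmentParams(config.gap_open, config.gap_extend)
    fcfg = FiltrationConfig(config.identity_threshold, config.fd_definition)

    qfv = frequency_vector(query, db.alphabet)
    filtration = apply_fdfs(qfv, len(query), db, fcfg)
    by_id = {r.id: r for r in filtration.records}
    selected = [s for s in db.entries if by_id[s.id].selected]
    n_exempt = sum(r.reason == "length_exempt" for r in filtration.records)
    n_rejected = len(db) - len(selected)
    log.info(
        "fdfs: %d total, %d length-exempt, %d fd-selected, %d rejected "
        "(identity %.2f, ed bound %d)",
        len(db), n_exempt, len(selected) - n_exempt, n_rejected,
        config.identity_threshold, filtration.ed_bound,
    )
    if not selected:
        log.warning("no database sequences selected; empty result")

    scores: dict[str, int] = {}
    for start in range(0, len(selected), config.batch_size):
        batch = selected[start : start + config.batch_size]
        for seq, score in zip(
            batch, batch_scores(query, batch, matrix, params,
                                workers=config.workers)
        ):
            scores[seq.id] = score

    results = [
        SearchResult(query.id, r.id, r.length, r.fd, True, scores[r.id])
        for r in filtration.records
        if r.selected
    ]
    results.sort(key=lambda r: (-r.score, r.db_id))
    if config.emit_filtered:
        filtered = [
            SearchResult(query.id, r.id, r.length, r.fd, False, None)
            for r in filtration.records
            if not r.selected
        ]
        filtered.sort(key=lambda r: r.db_id)
        results.extend(filtered)

    if config.output_path:
        write_results_tsv(results, config.output_path)
    log.info("search finished in %.2f s (%d rows)",
             time.monotonic() - t0, len(results))
    return results


def write_results_tsv(results, path) -> None:
    """Columns: query_id, db_id, length, fd, selected, score; NA for undefined."""
    with open(path, "w") as fh:
        fh.write("query_id\tdb_id\tlength\tfd\tselected\tscore\n")
        for r in results:
            fd = "NA" if r.fd is None else str(r.fd)
            score = "NA" if r.score is None else str(r.score)
            fh.write(
                f"{r.query_id}\t{r.db_id}\t{r.length}\t{fd}\t"
                f"{'true' if r.selected else 'false'}\t{score}\n"
            )
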