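"""Bundled reference tables.

The package ships the published five-outcome classification counts for
the placental-root analysis (11,169 genes; binned supergene trees and
unbinned gene trees at 50% and 75% bootstrap collapse thresholds) so the
support-fraction and coalescent-length computations can be exercised and
checked without the genome-scale inputs.
"""

from __future__ import annotations

from importlib import resources

from .concordance import ConcordanceTable, INDECISIVE, REJECTS_ALL

__all__ = ["load_root_count_tables"]

_ANALYSES = ("binned_50", "unbinned_50", "binned_75", "unbinned_75")


def load_root_count_tables() -> dict[str, ConcordanceTable]:
    """Load the published placental-root outcome counts.

    Returns one :class:`ConcordanceTable` per analysis variant, keyed by
    ``binned_50``, ``unbinned_50``, ``binned_75`` and ``unbinned_75``.
    """
    text = (
        resources.files("rootquartet.data")
        .joinpath("placental_root_counts.tsv")
        .read_text()
    )
    rows: dict[str, list[float]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    assert header == list(_ANALYSES)
    tables = {}
    hyp_names = [k for k in rows if k not in (REJECTS_ALL, INDECISIVE)]
    for j, analysis in enumerate(_ANALYSES):
        threshold = 50.0 if analysis.endswith("50") else 75.0
        tables[analysis] = ConcordanceTable.from_counts(
            {h: rows[h][j] for h in hyp_names},
            rejects_all=rows[REJECTS_ALL][j],
            indecisive=rows[INDECISIVE][j],
            threshold=threshold,
        )
    return tables
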