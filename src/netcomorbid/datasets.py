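"""Bundled curated tables.

Small published association grids between the hyperglycemia gene network
and the interactor neighborhoods of SARS-CoV-2 entry proteins (ACE2, DPP4,
CTSB, CTSL), shipped as plain TSV so worked examples and validation run
without downloads.
"""

from __future__ import annotations

from importlib import resources

from .crosstalk import CrosstabTable, TargetCategory
from .model import ConditionCategory, NetworkParseError, normalize_symbol

__all__ = ["available_crosstabs", "load_crosstab"]

_CROSSTAB_FILES = {
    "ACE2": "crosstab_ace2_hyperglycemia.tsv",
    "DPP4": "crosstab_dpp4_hyperglycemia.tsv",
    "CTSB": "crosstab_ctsb_hyperglycemia.tsv",
    "CTSL": "crosstab_ctsl_hyperglycemia.tsv",
}


def available_crosstabs() -> list[str]:
    """Targets with a bundled hyperglycemia crosstab."""
    return sorted(_CROSSTAB_FILES)


def parse_crosstab_tsv(
    text: str, condition: str, target: str
) -> CrosstabTable:
    """Parse a ``row<TAB>column<TAB>gene,gene,...`` crosstab grid."""
    cells: dict[tuple[TargetCategory, ConditionCategory], frozenset[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise NetworkParseError(
                f"line {lineno}: expected row<TAB>column<TAB>genes, got {len(fields)} fields"
            )
        row_tok, col_tok, genes_tok = (f.strip() for f in fields)
        try:
            key = (TargetCategory(row_tok), ConditionCategory(col_tok))
        except ValueError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
        genes = frozenset(
            normalize_symbol(g) for g in genes_tok.split(",") if g.strip()
        )
        if key in cells:
            raise NetworkParseError(f"line {lineno}: duplicate cell {key}")
        if genes:
            cells[key] = genes
    return CrosstabTable(condition=condition, target=target, cells=cells)


def load_crosstab(target: str) -> CrosstabTable:
    """Load the bundled hyperglycemia crosstab for one entry protein."""
    tgt = target.upper()
    if tgt not in _CROSSTAB_FILES:
        raise KeyError(
            f"no bundled crosstab for {target!r}; available: {available_crosstabs()}"
        )
    text = (
        resources.files("netcomorbid.data")
        .joinpath(_CROSSTAB_FILES[tgt])
        .read_text(encoding="utf-8")
    )
    return parse_crosstab_tsv(text, condition="hyperglycemia", target=tgt)
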