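"""Shared helpers: gene-id normalisation and package logging."""

from __future__ import annotations

import logging

logger = logging.getLogger("pathnet")


def normalize_gene_id(gene_id: str) -> str:
    """Canonicalise a gene identifier.

    Glyma-style identifiers are case-inconsistent across annotation sources
    (``Glyma.02g222400`` vs ``Glyma.14G127800``), so every identifier is
    whitespace-stripped and lower-cased before any set intersection.
    """
    return gene_id.strip().lower()


def normalize_gene_ids(gene_ids) -> list[str]:
    return [normalize_gene_id(g) for g in gene_ids]
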