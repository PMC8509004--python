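"""Sub-structural compartment roll-ups of the screen.

Each panel gene is annotated with one or more cilia compartments (axoneme,
basal body, transition zone, IFT complexes, GPCRs, ...).  This module rolls
DEGA calls up to compartment level: counts, percentages and direction
breakdowns, either per region or for the whole screen (scope ``ALL``, where
a gene counts as DEGA if it is one in at least one region).

Multi-compartment genes are counted once per compartment, so compartment
totals are not a partition of the panel.  At ALL scope a gene's direction is
the majority direction across its DEGA regions; exact ties go to a separate
``mixed`` bucket rather than being forced either way.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .age_screen import DegaSets
from .data_io import COMPARTMENTS, GeneAnnotation, GeneListError

log = logging.getLogger(__name__)

ALL_SCOPE = "ALL"


def _compartment_map(
    annotations: Iterable[GeneAnnotation],
    screened_genes: Iterable[str] | None,
    missing: str,
) -> dict[str, frozenset[str]]:
    lookup = {a.symbol: a.compartments for a in annotations}
    if screened_genes is None:
        return lookup
    out: dict[str, frozenset[str]] = {}
    for gene in screened_genes:
        if gene in lookup:
            out[gene] = lookup[gene]
        elif missing == "other":
            log.warning("gene %s lacks an annotation; assigning 'other'", gene)
            out[gene] = frozenset({"other"})
        else:
            raise GeneListError(f"no compartment annotation for {gene}")
    return out


def _all_scope_direction(gene: str, dega_sets: DegaSets) -> str:
    ups = sum(
        1 for r in dega_sets.regions
        if dega_sets.by_region[r].get(gene) == "up"
    )
    downs = sum(
        1 for r in dega_sets.regions
        if dega_sets.by_region[r].get(gene) == "down"
    )
    if ups > downs:
        return "up"
    if downs > ups:
        return "down"
    return "mixed"


def compartment_summary(
    dega_sets: DegaSets,
    annotations: Iterable[GeneAnnotation],
    scope: str = ALL_SCOPE,
    screened_genes: Iterable[str] | None = None,
    missing: str = "other",
) -> pd.DataFrame:
    """Per-compartment DEGA counts and percentages at one scope.

    ``scope`` is a region code or ``ALL``.  ``screened_genes`` defaults to
    every annotated symbol; the denominator ``n_total`` is the number of
    screened genes annotated to the compartment.  ``missing`` controls
    unannotated screened genes: ``"other"`` (warn and assign) or
    ``"error"``.

    Columns: compartment, scope, n_total, n_dega, n_up, n_down, n_mixed,
    pct_dega.  ``n_mixed`` (genes with tied directions across regions) is
    only populated at ALL scope.
    """
    annotations = list(annotations)
    comp_of = _compartment_map(annotations, screened_genes, missing)
    if scope == ALL_SCOPE:
        union = dega_sets.union_genes()
        membership = {g: _all_scope_direction(g, dega_sets) for g in union}
    else:
        if scope not in dega_sets.by_region:
            raise KeyError(f"unknown scope: {scope!r}")
        membership = dict(dega_sets.by_region[scope])

    rows = []
    order = [c for c, _ in _CANONICAL_ORDER if c in _present(comp_of)]
    for compartment in order:
        genes = [g for g, comps in comp_of.items() if compartment in comps]
        hits = {g: membership[g] for g in genes if g in membership}
        n_total = len(genes)
        n_dega = len(hits)
        directions = list(hits.values())
        rows.append(
            {
                "compartment": compartment,
                "scope": scope,
                "n_total": n_total,
                "n_dega": n_dega,
                "n_up": directions.count("up"),
                "n_down": directions.count("down"),
                "n_mixed": directions.count("mixed"),
                "pct_dega": 100.0 * n_dega / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compartment_summary_by_region(
    dega_sets: DegaSets,
    annotations: Iterable[GeneAnnotation],
    screened_genes: Iterable[str] | None = None,
    missing: str = "other",
) -> pd.DataFrame:
    """Long-format compartment summary over every region."""
    frames = [
        compartment_summary(
            dega_sets, annotations, scope=region,
            screened_genes=screened_genes, missing=missing,
        )
        for region in dega_sets.regions
    ]
    return pd.concat(frames, ignore_index=True)


def direction_breakdown(
    dega_sets: DegaSets,
    annotations: Iterable[GeneAnnotation],
    compartment: str,
) -> pd.DataFrame:
    """Per-region up/down fractions of one compartment's DEGAs.

    Regions with no DEGA in the compartment report NaN fractions (undefined,
    not zero).  Columns: region, n_dega, frac_up, frac_down.
    """
    if compartment not in COMPARTMENTS:
        raise KeyError(f"unknown compartment: {compartment!r}")
    members = {
        a.symbol for a in annotations if compartment in a.compartments
    }
    rows = []
    for region in dega_sets.regions:
        hits = {
            g: d for g, d in dega_sets.by_region[region].items()
            if g in members
        }
        n = len(hits)
        ups = sum(1 for d in hits.values() if d == "up")
        rows.append(
            {
                "region": region,
                "n_dega": n,
                "frac_up": ups / n if n else np.nan,
                "frac_down": (n - ups) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# Display order for compartments (structural base -> transport -> signalling).
_CANONICAL_ORDER: tuple[tuple[str, None], ...] = tuple(
    (c, None)
    for c in (
        "axoneme", "basal body", "transition zone", "centrosome",
        "kinesin", "dynein", "IFT-A", "IFT-B", "BBSome",
        "ciliary membrane", "GPCR", "Golgi", "cytosol", "nucleus",
        "mitochondria", "other",
    )
)


def _present(comp_of: dict[str, frozenset[str]]) -> set[str]:
    out: set[str] = set()
    for comps in comp_of.values():
        out.update(comps)
    return out
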