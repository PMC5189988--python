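"""A minimal atom-selection grammar.

Queries are conjunctions of clauses joined by ``and``.  Each clause is a
keyword followed by one or more values (values within a clause are OR-ed):

    name CA
    resid 44 and name OG
    chain A and resname ALA GLY
    resid 10:25 and name CA

Keywords: ``name``, ``resname``, ``chain``, ``resid`` (single ids or
``start:end`` / ``start-end`` inclusive ranges), ``element``.  Matching is
case-insensitive for element symbols and exact (stripped) for names.
An empty result is allowed and reported with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import AtomSelection, SelectionError, Structure

_KEYWORDS = {"name", "resname", "chain", "resid", "element"}


def _parse_resid_values(tokens: list[str], query: str) -> list[tuple[int, int]]:
    ranges = []
    for tok in tokens:
        try:
            if ":" in tok:
                lo, hi = tok.split(":")
                ranges.append((int(lo), int(hi)))
            elif "-" in tok[1:]:  # allow a leading minus on the low bound
                pos = tok.index("-", 1)
                ranges.append((int(tok[:pos]), int(tok[pos + 1:])))
            else:
                v = int(tok)
                ranges.append((v, v))
        except ValueError as exc:
            raise SelectionError(f"bad resid token {tok!r} in query {query!r}") from exc
    return ranges


def select(s: Structure, query: str) -> AtomSelection:
    """Evaluate a selection query against a structure.

    Returns an order-preserving (hence sorted) index list.  Raises
    :class:`SelectionError` for anything outside the grammar.
    """
    if not isinstance(query, str) or not query.strip():
        raise SelectionError("empty selection query")
    mask = np.ones(s.n_atoms, dtype=bool)
    clauses = [c.strip() for c in query.split(" and ")]
    for clause in clauses:
        tokens = clause.split()
        if len(tokens) < 2:
            raise SelectionError(f"cannot parse clause {clause!r} in {query!r}")
        key, values = tokens[0].lower(), tokens[1:]
        if key not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {tokens[0]!r}")
        if key == "resid":
            ranges = _parse_resid_values(values, query)
            resids = np.array([a.resid for a in s.atoms])
            cm = np.zeros(s.n_atoms, dtype=bool)
            for lo, hi in ranges:
                cm |= (resids >= lo) & (resids <= hi)
        elif key == "name":
            names = np.array([a.name.strip() for a in s.atoms])
            cm = np.isin(names, values)
        elif key == "resname":
            rn = np.array([a.resname.strip().upper() for a in s.atoms])
            cm = np.isin(rn, [v.upper() for v in values])
        elif key == "chain":
            ch = np.array([a.chain.strip() for a in s.atoms])
            cm = np.isin(ch, values)
        else:  # element
            el = np.array([a.element.strip().upper() for a in s.atoms])
            cm = np.isin(el, [v.upper() for v in values])
        mask &= cm
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {query!r} matched no atoms")
    return AtomSelection(idx, label=query)


def ca_selection(s: Structure) -> AtomSelection:
    """Convenience: all Calpha atoms, one per (protein) residue."""
    return select(s, "name CA")
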