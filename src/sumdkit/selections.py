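"""A small atom-selection language and named backbone presets.

Grammar (whitespace-tokenised, case-sensitive values)::

    expression := clause ("and" clause)*
    clause     := "chain"     ID+
                | "resid"     RANGE+        # 5  or  788-791
                | "resname"   NAME+
                | "name"      NAME+
                | "component" (receptor|ligand|other)+
                | "protein_backbone" | "nucleic_backbone"   # name presets
                | "all"

All clauses of an expression must hold simultaneously (conjunction).  A
clause that matches no atom raises, naming the offending clause, so typos
in residue lists fail loudly instead of silently shrinking a supervision
group.
"""

from __future__ import annotations

import numpy as np

from .topology import Component, MolecularSystem, Selection

#: Default protein-backbone atom names (overridable via ``presets=``).
PROTEIN_BACKBONE = ("N", "CA", "C", "O")
#: Default nucleic-acid backbone atom names.
NUCLEIC_BACKBONE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'")

_KEYWORDS = {
    "chain",
    "resid",
    "resname",
    "name",
    "component",
    "all",
    "and",
    "protein_backbone",
    "nucleic_backbone",
}


def _parse_ranges(tokens: list[str], clause: str) -> list[tuple[int, int]]:
    out = []
    for tok in tokens:
        lo, dash, hi = tok.partition("-") if not tok.startswith("-") else (tok, "", "")
        try:
            if dash:
                out.append((int(lo), int(hi)))
            else:
                v = int(tok)
                out.append((v, v))
        except ValueError as exc:
            raise ValueError(f"bad residue range {tok!r} in clause {clause!r}") from exc
    return out


def build_selection(
    system: MolecularSystem,
    expression: str,
    label: str | None = None,
    presets: dict[str, tuple[str, ...]] | None = None,
) -> Selection:
    """Evaluate a selection expression against a system.

    Returns all matching atom ids in ascending order; the expression is
    recorded on the Selection so it can be re-applied verbatim.
    """
    names = {
        "protein_backbone": PROTEIN_BACKBONE,
        "nucleic_backbone": NUCLEIC_BACKBONE,
    }
    if presets:
        names.update(presets)

    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")

    # split into clauses on "and"
    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok == "and":
            if not clauses[-1]:
                raise ValueError(f"misplaced 'and' in {expression!r}")
            clauses.append([])
        else:
            clauses[-1].append(tok)
    if not clauses[-1]:
        raise ValueError(f"trailing 'and' in {expression!r}")

    mask = np.ones(system.n_atoms, dtype=bool)
    for clause in clauses:
        key, args = clause[0], clause[1:]
        text = " ".join(clause)
        if key == "all":
            sub = np.ones(system.n_atoms, dtype=bool)
        elif key in ("protein_backbone", "nucleic_backbone"):
            wanted = set(names[key])
            sub = np.array([a.name in wanted for a in system.atoms])
        elif key == "chain":
            sub = np.array([a.chain_id in args for a in system.atoms])
        elif key == "resname":
            sub = np.array([a.residue_name in args for a in system.atoms])
        elif key == "name":
            sub = np.array([a.name in args for a in system.atoms])
        elif key == "component":
            comps = {Component(v) for v in args}
            sub = np.array([a.component in comps for a in system.atoms])
        elif key == "resid":
            ranges = _parse_ranges(args, text)
            sub = np.array(
                [any(lo <= a.residue_index <= hi for lo, hi in ranges) for a in system.atoms]
            )
        else:
            raise ValueError(f"unknown selection keyword {key!r} in {expression!r}")
        if key != "all" and not args and key not in ("protein_backbone", "nucleic_backbone"):
            raise ValueError(f"clause {text!r} has no arguments")
        if not sub.any():
            raise ValueError(f"clause {text!r} matches no atom")
        mask &= sub

    ids = np.flatnonzero(mask)
    if ids.size == 0:
        raise ValueError(f"expression {expression!r} matches no atom")
    return Selection(atom_ids=ids, label=label or expression, expression=expression)
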