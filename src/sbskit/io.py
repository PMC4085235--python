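"""Plain-text model files and delimited ensemble/trajectory output.

Model grammar (one statement per line; ``#`` starts a comment)::

    species X1 X2 X3
    init X1=10000 X2=1 X3=0
    fixed A B                      # optional
    T 5.0
    r decay1 : 1 X1 -> 1 X2 ; c=1.0
    r bind   : EA + B <-> EAB ; c=5e-4, 2.0   # reversible, forward first

Multiplicities default to 1; ``0`` or an empty side denotes no species
(e.g. ``A -> 0``).  Reversible reactions expand into two irreversible ones,
forward rate first.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path

import numpy as np

from .model import ReactionSystem, StateVector, build_system


class ModelSyntaxError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


_SIDE_TOKEN = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_]\w*)$")


def _parse_side(text: str, line_no: int) -> dict[str, int]:
    text = text.strip()
    if text in ("", "0", "∅"):
        return {}
    out: dict[str, int] = {}
    for part in text.split("+"):
        m = _SIDE_TOKEN.match(part.strip())
        if not m:
            raise ModelSyntaxError(line_no, f"cannot parse species term {part.strip()!r}")
        mult = int(m.group(1) or 1)
        name = m.group(2)
        out[name] = out.get(name, 0) + mult
    return out


def parse_model(text: str) -> tuple[ReactionSystem, StateVector, float]:
    """Parse a model description; returns (system, initial state, horizon)."""
    species: list[str] = []
    init: dict[str, int] = {}
    fixed: list[str] = []
    horizon: float | None = None
    reactions: list[dict] = []
    names_seen: set[str] = set()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(" ")
        if head == "species":
            species.extend(rest.split())
        elif head == "init":
            for tok in rest.split():
                name, _, val = tok.partition("=")
                if not val:
                    raise ModelSyntaxError(line_no, f"bad init token {tok!r}")
                init[name] = int(val)
        elif head == "fixed":
            fixed.extend(rest.split())
        elif head == "T":
            horizon = float(rest)
        elif head == "r":
            name, _, body = rest.partition(":")
            name = name.strip()
            if not name:
                raise ModelSyntaxError(line_no, "reaction needs a name before ':'")
            if name in names_seen:
                raise ModelSyntaxError(line_no, f"duplicate reaction name {name!r}")
            names_seen.add(name)
            body, _, rate_part = body.partition(";")
            rate_part = rate_part.strip()
            if not rate_part.startswith("c="):
                raise ModelSyntaxError(line_no, "missing '; c=<value>'")
            rates = [float(v) for v in rate_part[2:].split(",")]
            reversible = "<->" in body
            arrow = "<->" if reversible else "->"
            lhs_txt, sep, rhs_txt = body.partition(arrow)
            if not sep:
                raise ModelSyntaxError(line_no, "missing reaction arrow")
            rx = {
                "name": name,
                "reactants": _parse_side(lhs_txt, line_no),
                "products": _parse_side(rhs_txt, line_no),
                "c": rates[0],
            }
            if reversible:
                if len(rates) != 2:
                    raise ModelSyntaxError(line_no, "reversible reaction needs two rates")
                rx["c_rev"] = rates[1]
            elif len(rates) != 1:
                raise ModelSyntaxError(line_no, "irreversible reaction takes one rate")
            reactions.append(rx)
        else:
            raise ModelSyntaxError(line_no, f"unknown statement {head!r}")

    if horizon is None:
        raise ValueError("model file missing a 'T' stanza")
    for rx in reactions:
        for name in list(rx["reactants"]) + list(rx["products"]):
            if name not in species:
                raise ValueError(f"reaction {rx['name']!r} references unknown species {name!r}")
    sys = build_system(species, reactions, fixed=fixed)
    counts = np.array([init.get(s, 0) for s in species], dtype=np.int64)
    return sys, StateVector(counts), horizon


def parse_model_file(path: str | Path) -> tuple[ReactionSystem, StateVector, float]:
    return parse_model(Path(path).read_text())


def write_model(
    sys: ReactionSystem, x0: StateVector, T: float, reaction_names: list[str] | None = None
) -> str:
    """Serialise a system back to the model grammar (round-trips parse)."""
    lines = ["species " + " ".join(sys.species_names)]
    lines.append(
        "init " + " ".join(f"{s}={int(v)}" for s, v in zip(sys.species_names, x0.counts))
    )
    if sys.fixed_species.any():
        lines.append(
            "fixed " + " ".join(np.array(sys.species_names)[sys.fixed_species])
        )
    lines.append(f"T {T:g}")
    for j in range(sys.n_reactions):
        name = reaction_names[j] if reaction_names else f"r{j + 1}"

        def side(col: np.ndarray) -> str:
            terms = [
                (f"{col[i]} " if col[i] != 1 else "") + sys.species_names[i]
                for i in np.nonzero(col)[0]
            ]
            return " + ".join(terms) if terms else "0"

        lhs = sys.reactant_orders[:, j]
        rhs = sys.reactant_orders[:, j] + sys.net_change[:, j]
        lines.append(
            f"r {name} : {side(lhs)} -> {side(rhs)} ; c={sys.rate_constants[j]:g}"
        )
    return "\n".join(lines) + "\n"


def manifest_hash(settings: dict) -> str:
    payload = repr(sorted(settings.items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_ensemble(
    path: str | Path,
    finals: np.ndarray,
    species_names: list[str],
    manifest: dict,
) -> None:
    """Final-state ensemble as a tab-delimited table with a manifest header."""
    path = Path(path)
    lines = [f"# {k} = {v}" for k, v in sorted(manifest.items())]
    lines.append(f"# manifest_hash = {manifest_hash(manifest)}")
    lines.append("\t".join(species_names))
    for row in np.atleast_2d(finals):
        lines.append("\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_ensemble(path: str | Path) -> tuple[np.ndarray, list[str]]:
    rows = []
    header: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if not header:
            header = line.split("\t")
            continue
        rows.append([int(v) for v in line.split("\t")])
    return np.array(rows, dtype=np.int64), header
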