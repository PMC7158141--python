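"""Model and result input/output.

Two model formats are supported:

* **SBML** Level 3 with the FBC package, read through ``cobrapy``.
  Reversibility is taken from the FBC flux bounds: a reaction is
  irreversible iff its lower bound is >= 0 (the SBML ``reversible``
  attribute is ignored when bounds are present — the bounds are the
  operative constraint).
* A **JSON dialect** documented here: an object with keys

  - ``metabolites``: list of metabolite id strings (row order),
  - ``reactions``: list of ``{"id": str, "irreversible": bool,
    "lower": float?, "upper": float?}`` (column order),
  - ``stoichiometry``: sparse triplet list ``[[row, col, coeff], ...]``.

Core sets are UTF-8 text, one reaction id per line; ``#`` starts a
comment.  Reports are JSON plus a plain reaction-id list, linked by
identifier (never by position) so files can reorder freely.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Union

import numpy as np
import scipy.sparse as sp

from .model import CoreSet, MetabolicNetwork, ValidationError

__all__ = [
    "load_model",
    "save_model_json",
    "load_core_set",
    "save_report",
    "FormatError",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A model file failed to parse; the message names the offending
    element."""


def load_model(path: PathLike, format: str | None = None) -> MetabolicNetwork:
    """Load a model from SBML or the JSON dialect.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred
    from the file suffix (.xml/.sbml -> SBML, .json -> JSON).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".xml", ".sbml"):
            format = "sbml"
        elif suffix == ".json":
            format = "json"
        else:
            raise FormatError(f"cannot infer model format from {path.name!r}")
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise FormatError(f"unknown model format {format!r}")


def _load_json(path: Path) -> MetabolicNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    for key in ("metabolites", "reactions", "stoichiometry"):
        if key not in doc:
            raise FormatError(f"missing key {key!r} in {path}")
    mids = [str(x) for x in doc["metabolites"]]
    rids, irrev, lowers, uppers, have_bounds = [], [], [], [], False
    for k, rxn in enumerate(doc["reactions"]):
        if "id" not in rxn or "irreversible" not in rxn:
            raise FormatError(f"reaction #{k} lacks 'id' or 'irreversible'")
        rids.append(str(rxn["id"]))
        irrev.append(bool(rxn["irreversible"]))
        if "lower" in rxn or "upper" in rxn:
            have_bounds = True
        lowers.append(float(rxn.get("lower", -np.inf)))
        uppers.append(float(rxn.get("upper", np.inf)))
    rows, cols, vals = [], [], []
    for t, triple in enumerate(doc["stoichiometry"]):
        try:
            i, j, c = triple
        except (TypeError, ValueError):
            raise FormatError(f"stoichiometry entry #{t} is not a triplet")
        rows.append(int(i)); cols.append(int(j)); vals.append(float(c))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(mids), len(rids)), dtype=float
    )
    bounds = np.column_stack([lowers, uppers]) if have_bounds else None
    return MetabolicNetwork(mids, rids, S, np.array(irrev), bounds=bounds)


def _load_sbml(path: Path) -> MetabolicNetwork:
    from cobra.io import read_sbml_model

    try:
        model = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"failed to parse SBML {path}: {exc}") from exc
    mids = [met.id for met in model.metabolites]
    met_index = {mid: i for i, mid in enumerate(mids)}
    rids, irrev, rows, cols, vals, bounds = [], [], [], [], [], []
    for j, rxn in enumerate(model.reactions):
        rids.append(rxn.id)
        irrev.append(rxn.lower_bound >= 0)
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        for met, coeff in rxn.metabolites.items():
            rows.append(met_index[met.id]); cols.append(j)
            vals.append(float(coeff))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(mids), len(rids)), dtype=float
    )
    return MetabolicNetwork(
        mids, rids, S, np.array(irrev), bounds=np.array(bounds)
    )


def save_model_json(net: MetabolicNetwork, path: PathLike) -> None:
    """Write the JSON dialect; a save->load round trip reproduces ``S``
    exactly (Python serializes floats losslessly)."""
    coo = net.S.tocoo()
    doc: dict[str, Any] = {
        "metabolites": net.metabolite_ids,
        "reactions": [
            {"id": rid, "irreversible": bool(net.irreversible[j]),
             **({"lower": net.bounds[j, 0], "upper": net.bounds[j, 1]}
                if net.bounds is not None else {})}
            for j, rid in enumerate(net.reaction_ids)
        ],
        "stoichiometry": [
            [int(i), int(j), float(v)]
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_core_set(path: PathLike, net: MetabolicNetwork) -> CoreSet:
    """Read a core set: one reaction id per line, '#' comments."""
    ids = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return CoreSet.from_ids(net, ids)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_report(report: dict[str, Any], path: PathLike,
                reaction_list: Iterable[str] | None = None) -> None:
    """Serialize a result dictionary to JSON; when ``reaction_list`` is
    given also write a sibling ``.txt`` with one reaction id per line."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=1))
    if reaction_list is not None:
        txt = path.with_suffix(".txt")
        txt.write_text("\n".join(reaction_list) + "\n")
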