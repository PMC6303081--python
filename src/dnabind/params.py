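"""Loading and applying the shipped force-field parameter table."""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files

COULOMB_CONSTANT = 332.0636  # kcal A / (mol e^2)


class ParameterError(KeyError):
    """An atom without an entry in the parameter table."""


@lru_cache(maxsize=1)
def load_parameter_table() -> dict:
    """(residue, atom) -> (charge, rmin_half, epsilon, pb_radius)."""
    text = (files("dnabind") / "data" / "ff_params.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        res, atom, q, rmin, eps, pb = line.split("\t")
        table[(res, atom)] = (float(q), float(rmin), float(eps), float(pb))
    return table


def parameterize(structure) -> None:
    """Assign charge/LJ/PB parameters to every atom in place."""
    table = load_parameter_table()
    for res in structure.residues():
        for a in res.atoms:
            try:
                q, rmin, eps, pb = table[(res.name, a.name)]
            except KeyError:
                raise ParameterError(
                    f"no parameters for atom {a.name!r} of residue {res.label}"
                ) from None
            a.partial_charge = q
            a.lj_rmin_half = rmin
            a.lj_epsilon = eps
            a.pb_radius = pb


def net_charge(structure) -> float:
    return sum(a.partial_charge for a in structure.atoms())
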