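"""End-to-end prediction workflow for one complex and a mutation list.

Mirrors the serving workflow of the method: parse the complex, assign
partners (protein = partner 1, DNA = partner 2), complete heavy atoms and
protonate, minimize the wild type once; then for each mutation
independently build the mutant side chain, protonate, minimize, compute the
nine features from the minimized pair, evaluate the linear model, and
classify the mutation as deleterious when the predicted ddG is >= 1.10
kcal/mol.  Each prediction row also reports whether the site is an
interface residue, and the minimized mutant model is returned for writing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd

from .forcefield import MinimizationSettings, minimize
from .hbonds import HBondCriteria
from .model import MLRModel, classify_deleterious, DELETERIOUS_DDG_PRED
from .mutator import build_mutant
from .pbsolver import PBSettings
from .energetics import assemble_features, FEATURE_NAMES
from .structure import (
    ComplexStructure, Mutation, StructureError,
    add_hydrogens, complete_heavy_atoms,
)

logger = logging.getLogger(__name__)

MAX_MUTATIONS = 16


def default_model() -> MLRModel:
    """The shipped model, trained on the synthetic reference dataset.

    The method's published regression weights are not distributed with the
    original work, so the packaged default is trained on this package's own
    synthetic feature tables: it demonstrates the method end to end and is
    meant to be retrained on curated experimental data for production use.
    """
    return MLRModel.from_json(
        (files("dnabind") / "data" / "default_model.json").read_text())


@dataclass
class PredictionResult:
    mutation: Mutation
    features: dict
    ddg_pred: float
    interface: bool
    deleterious: bool
    mutant_structure: ComplexStructure


@dataclass
class PredictionRun:
    wild_min: ComplexStructure
    results: list = field(default_factory=list)
    energy_traces: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "mutation": str(r.mutation),
                "ddg_pred": round(r.ddg_pred, 2),
                "interface": "yes" if r.interface else "no",
                "deleterious": "yes" if r.deleterious else "no",
                **{k: r.features[k] for k in FEATURE_NAMES},
            })
        return pd.DataFrame(rows)


def prepare_wild_type(structure: ComplexStructure) -> ComplexStructure:
    """Complete missing heavy side-chain atoms and protonate."""
    return add_hydrogens(complete_heavy_atoms(structure))


def predict_mutations(structure: ComplexStructure, mutations,
                      model: MLRModel | None = None,
                      pb_settings: PBSettings = PBSettings(),
                      min_settings: MinimizationSettings = MinimizationSettings(),
                      criteria: HBondCriteria = HBondCriteria(),
                      threshold: float = DELETERIOUS_DDG_PRED,
                      ) -> PredictionRun:
    """Predict ddG for up to 16 single mutations on one complex.

    ``structure`` must already have partners assigned (see
    :func:`dnabind.structure.assign_partners`).  Mutations are processed
    independently; every mutation is validated against the wild-type
    sequence before any expensive work starts.
    """
    mutations = [Mutation.parse(m) if isinstance(m, str) else m
                 for m in mutations]
    if not mutations:
        raise ValueError("no mutations given")
    if len(mutations) > MAX_MUTATIONS:
        raise ValueError(
            f"at most {MAX_MUTATIONS} mutations per run (got {len(mutations)})")
    if not structure.partner1 or not structure.partner2:
        raise StructureError("assign partners before predicting")
    model = model or default_model()

    wild = prepare_wild_type(structure)
    for m in mutations:
        build_mutant(wild, m)   # validates address and wild-type identity

    logger.info("minimizing wild-type complex (%d atoms)", wild.n_atoms)
    wild_min, wt_trace = minimize(wild, min_settings)
    run = PredictionRun(wild_min=wild_min, energy_traces={"wild": wt_trace})

    for m in mutations:
        logger.info("mutation %s: building mutant", m)
        mutant = add_hydrogens(build_mutant(wild, m))
        mut_min, trace = minimize(mutant, min_settings)
        run.energy_traces[str(m)] = trace
        fv = assemble_features(wild_min, mut_min, m, pb_settings, criteria)
        ddg = float(model.predict(fv))
        result = PredictionResult(
            mutation=m,
            features=fv.as_dict(),
            ddg_pred=ddg,
            interface=bool(fv.location_mut >= 0.5),
            deleterious=classify_deleterious(ddg, threshold),
            mutant_structure=mut_min,
        )
        logger.info("mutation %s: ddG = %+.2f kcal/mol (%s)", m, ddg,
                    "deleterious" if result.deleterious else "tolerated")
        for k in FEATURE_NAMES:
            logger.info("  %-20s %12.4f", k, result.features[k])
        run.results.append(result)
    return run
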