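"""Named, logged analysis recipes over user-supplied structure files.

Each recipe reproduces one published contact/geometry analysis as a
deterministic table: EH2↔NPF-peptide contacts, contact comparison across the
two EH2–peptide complexes, the αC/H8 overlap at the Gα-peptide site, the
Gγ-NPF-proline→Cys316 distance, the receptor C-tail occlusion of the
TM1/ICL1/H8 pocket, the dimer interface, and R-/T-state contact persistence.

Structure files are never downloaded: a missing input is an error naming the
accession and its role.  Chain roles vary between depositions, so they are
declared in the config rather than guessed.  Reports record input checksums,
the model index and the hydrogen policy, and rerunning a recipe on identical
inputs yields byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

from .contacts import contact_persistence, interchain_contacts, intrachain_interactions, min_distance
from .structure_io import Selection, StructureModel, read_structure

__all__ = ["RecipeConfig", "RecipeReport", "RecipeInputError", "run_recipe", "RECIPES"]

log = logging.getLogger(__name__)

#: entries deposited with hydrogens; recipes keep them by default to mirror
#: the published contact counts (override with options.keep_hydrogens)
HYDROGEN_BEARING = frozenset({"1F8H", "1FF1", "6OFJ"})


class RecipeInputError(FileNotFoundError):
    pass


@dataclass
class RecipeConfig:
    """Inputs and options of one recipe run.

    ``inputs`` maps accession → local file path; ``chains`` maps accession →
    role → chain id (roles are recipe-specific, e.g. ``eh2``/``peptide`` or
    ``rhodopsin``/``gbeta``/``ggamma``); ``options`` carries cutoff,
    model_index, keep_hydrogens and recipe-specific residue numbers.
    """

    recipe: str
    inputs: dict[str, str] = field(default_factory=dict)
    chains: dict[str, dict[str, str]] = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RecipeConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            recipe=data["recipe"],
            inputs={str(k): str(v) for k, v in (data.get("inputs") or {}).items()},
            chains={
                str(k): {str(r): str(c) for r, c in v.items()}
                for k, v in (data.get("chains") or {}).items()
            },
            options=data.get("options") or {},
            output_dir=data.get("output_dir"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "recipe": self.recipe,
                "inputs": self.inputs,
                "chains": self.chains,
                "options": self.options,
                "output_dir": self.output_dir,
            },
            sort_keys=True,
        )


@dataclass
class RecipeReport:
    recipe: str
    inputs: dict[str, dict]  # accession -> {path, sha256}
    parameters: dict
    tables: dict[str, pd.DataFrame]
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{self.recipe}.{name}.tsv", sep="\t", index=False)
        meta = {
            "recipe": self.recipe,
            "inputs": self.inputs,
            "parameters": self.parameters,
            "log": self.log,
            "tables": sorted(self.tables),
        }
        (outdir / f"{self.recipe}.report.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )


class _Run:
    """Shared plumbing: input resolution, logging, parameter recording."""

    def __init__(self, config: RecipeConfig, required: Mapping[str, str]):
        self.config = config
        self.messages: list[str] = []
        self.inputs: dict[str, dict] = {}
        missing = [
            f"{acc} ({role})" for acc, role in required.items() if acc not in config.inputs
        ]
        if missing:
            raise RecipeInputError(
                f"recipe {config.recipe!r} needs input files for: {', '.join(missing)}"
            )
        for acc in required:
            path = Path(config.inputs[acc])
            if not path.exists():
                raise RecipeInputError(
                    f"recipe {config.recipe!r}: file for {acc} not found at {path}"
                )
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            self.inputs[acc] = {"path": str(path), "sha256": digest}

    def load(self, accession: str) -> StructureModel:
        opts = self.config.options
        keep_h = opts.get("keep_hydrogens", accession in HYDROGEN_BEARING)
        model_index = opts.get("model_index", 0)
        model = read_structure(
            self.config.inputs[accession],
            model_index=model_index,
            keep_hydrogens=keep_h,
        )
        self.info(
            f"loaded {accession}: model_index={model_index} keep_hydrogens={keep_h} "
            f"chains={sorted(model.chains)} atoms={model.n_atoms}"
        )
        return model

    def chain(self, accession: str, role: str) -> str:
        try:
            return self.config.chains[accession][role]
        except KeyError:
            raise KeyError(
                f"recipe {self.config.recipe!r}: declare chains[{accession!r}][{role!r}] "
                "in the config (chain roles are not guessed)"
            ) from None

    def info(self, message: str) -> None:
        self.messages.append(message)
        log.info("%s: %s", self.config.recipe, message)

    @property
    def cutoff(self) -> float:
        return float(self.config.options.get("cutoff", 4.0))

    def report(self, tables: dict[str, pd.DataFrame], **parameters) -> RecipeReport:
        params = {"cutoff": self.cutoff, **self.config.options, **parameters}
        return RecipeReport(
            recipe=self.config.recipe,
            inputs=self.inputs,
            parameters=params,
            tables=tables,
            log=self.messages,
        )


def _contact_tables(run: _Run, model, sel_a: Selection, sel_b: Selection):
    table = interchain_contacts(model, sel_a, sel_b, cutoff=run.cutoff)
    run.info(f"{len(table)} atom-pair contacts < {run.cutoff} Å")
    summary = pd.DataFrame(
        [
            {
                "chain_a": ka[0], "res_a": ka[1],
                "chain_b": kb[0], "res_b": kb[1],
                "min_distance": round(d, 3),
            }
            for (ka, kb), d in sorted(table.residue_pair_summary().items())
        ],
        columns=["chain_a", "res_a", "chain_b", "res_b", "min_distance"],
    )
    return table.to_frame(), summary


# ---------------------------------------------------------------------------
# the recipes


def _fig3_contacts(run: _Run) -> RecipeReport:
    """EH2 domain residues contacting the NPF tripeptide of the bound peptide."""
    model = run.load("1F8H")
    eh2 = run.chain("1F8H", "eh2")
    pep = run.chain("1F8H", "peptide")
    lo, hi = run.config.options.get("peptide_npf_range", (8, 10))
    sel_eh2 = Selection(model, eh2)
    sel_npf = Selection(model, pep, residue_range=(int(lo), int(hi)))
    contacts, summary = _contact_tables(run, model, sel_eh2, sel_npf)
    return run.report({"contacts": contacts, "residue_pairs": summary},
                      peptide_npf_range=[int(lo), int(hi)])


def _fig5_compare(run: _Run) -> RecipeReport:
    """EH2 contacts with the residues flanking NPF, compared across 1F8H/1FF1."""
    frames = []
    for acc in ("1F8H", "1FF1"):
        model = run.load(acc)
        eh2 = run.chain(acc, "eh2")
        pep = run.chain(acc, "peptide")
        flank = run.config.options.get("peptide_flank_residues", (6, 7, 11))
        sel_eh2 = Selection(model, eh2)
        sel_flank = Selection(model, pep, residue_numbers=frozenset(int(r) for r in flank))
        _, summary = _contact_tables(run, model, sel_eh2, sel_flank)
        summary.insert(0, "structure", acc)
        frames.append(summary)
    both = pd.concat(frames, ignore_index=True)
    return run.report({"comparison": both})


def _fig6_overlap(run: _Run) -> RecipeReport:
    """αC(SLE)↔STNPFR contacts next to H8(NKQ)↔Gα-H5 contacts."""
    tables: dict[str, pd.DataFrame] = {}
    model_r = run.load("3DQB")
    rho = run.chain("3DQB", "rhodopsin")
    galpha = run.chain("3DQB", "galpha_peptide")
    nkq = run.config.options.get("nkq_residues", (310, 311, 312))
    sel_nkq = Selection(model_r, rho, residue_numbers=frozenset(int(r) for r in nkq))
    _, tables["nkq_vs_galpha"] = _contact_tables(
        run, model_r, sel_nkq, Selection(model_r, galpha)
    )

    model_e = run.load("1F8H")
    eh2 = run.chain("1F8H", "eh2")
    pep = run.chain("1F8H", "peptide")
    sle = run.config.options.get("sle_residues")
    if sle:
        sel_sle = Selection(model_e, eh2, residue_numbers=frozenset(int(r) for r in sle))
        _, tables["sle_vs_peptide"] = _contact_tables(
            run, model_e, sel_sle, Selection(model_e, pep)
        )
    else:
        run.info("sle_residues not declared; only the Glu55-anchored comparison is text-"
                 "verified, skipping the αC triple table")
    return run.report(tables)


def _fig7_distance(run: _Run) -> RecipeReport:
    """Distance from the Gγ NPF proline side chain to rhodopsin Cys316 (8.53)."""
    model = run.load("6QNO")
    rho = run.chain("6QNO", "rhodopsin")
    gg = run.chain("6QNO", "ggamma")
    pro = int(run.config.options.get("ggamma_pro_residue", 63))
    cys = int(run.config.options.get("rhodopsin_cys_residue", 316))
    d = min_distance(
        Selection(model, gg, residue_range=(pro, pro), side_chain_only=True),
        Selection(model, rho, residue_range=(cys, cys)),
    )
    run.info(f"Gγ Pro{pro} side chain ↔ rhodopsin Cys{cys}: {d:.2f} Å")
    table = pd.DataFrame(
        [{"ggamma_pro": pro, "rhodopsin_cys": cys, "min_distance": round(d, 2)}]
    )
    return run.report({"distance": table}, ggamma_pro_residue=pro, rhodopsin_cys_residue=cys)


def _fig8_ctail(run: _Run) -> RecipeReport:
    """Receptor C-tail contacts with TM1/ICL1/H8 (pocket occlusion in the ground state)."""
    model = run.load("1U19")
    rho = run.chain("1U19", "rhodopsin")
    ctail = tuple(run.config.options.get("ctail_range", (335, 345)))
    pocket_ranges = [tuple(r) for r in run.config.options.get(
        "pocket_ranges", ((35, 64), (65, 70), (310, 323))
    )]
    frames = []
    for lo, hi in pocket_ranges:
        sel_ctail = Selection(model, rho, residue_range=(int(ctail[0]), int(ctail[1])))
        sel_pocket = Selection(model, rho, residue_range=(int(lo), int(hi)))
        _, summary = _contact_tables(run, model, sel_pocket, sel_ctail)
        summary.insert(0, "pocket_range", f"{lo}-{hi}")
        frames.append(summary)
    contacts = pd.concat(frames, ignore_index=True)
    typology = intrachain_interactions(
        model, rho, ranges=[(int(ctail[0]), int(ctail[1]))] + pocket_ranges
    )
    typ = pd.DataFrame(
        [
            {
                "res_a": r.residue_a[1], "resname_a": r.resname_a,
                "res_b": r.residue_b[1], "resname_b": r.resname_b,
                "type": r.type, "distance": r.distance,
            }
            for r in typology
        ],
        columns=["res_a", "resname_a", "res_b", "resname_b", "type", "distance"],
    )
    return run.report({"ctail_contacts": contacts, "interaction_types": typ},
                      ctail_range=list(ctail))


def _fig9_dimer(run: _Run) -> RecipeReport:
    """Protomer–protomer contacts of the receptor dimer interface."""
    model = run.load("6OFJ")
    a = run.chain("6OFJ", "protomer_a")
    b = run.chain("6OFJ", "protomer_b")
    contacts, summary = _contact_tables(run, model, Selection(model, a), Selection(model, b))
    return run.report({"contacts": contacts, "residue_pairs": summary})


def _fig10_states(run: _Run) -> RecipeReport:
    """R-state receptor↔Gβ contacts and their persistence in the T-state."""
    model_r = run.load("6QNO")
    rho = run.chain("6QNO", "rhodopsin")
    gbeta = run.chain("6QNO", "gbeta")
    ctail = tuple(run.config.options.get("ctail_range", (325, 348)))
    sel_ctail = Selection(model_r, rho, residue_range=(int(ctail[0]), int(ctail[1])))
    table = interchain_contacts(
        model_r, sel_ctail, Selection(model_r, gbeta), cutoff=run.cutoff
    )
    run.info(f"{len(table)} R-state C-tail↔Gβ atom contacts")

    model_t = run.load("1A0R")
    gbeta_t = run.chain("1A0R", "gbeta")
    model_t = _superpose_chain(model_t, gbeta_t, model_r, gbeta)
    run.info("superposed T-state Gβ onto the R-state Gβ frame (common-residue Cα)")
    mapping = {}
    for rec in table.records:
        for key in (rec.residue_a, rec.residue_b):
            if key[0] == gbeta:
                mapping[key] = (gbeta_t, key[1], key[2])
    # receptor-side residues have no T-state image: persistence is evaluated on
    # the Gβ conformational change with the receptor frame held fixed
    persistence = contact_persistence(
        table,
        _merge_models(model_r, rho, model_t, gbeta_t),
        mapping=mapping,
    )
    rows = pd.DataFrame(
        [
            {
                "res_a": f"{p.residue_a[0]}/{p.residue_a[1]}",
                "res_b": f"{p.residue_b[0]}/{p.residue_b[1]}",
                "distance_t_state": round(p.distance_in_alt, 3),
                "broken": bool(p.broken),
            }
            for p in persistence
        ],
        columns=["res_a", "res_b", "distance_t_state", "broken"],
    )
    return run.report({"contacts": table.to_frame(), "persistence": rows},
                      ctail_range=list(ctail))


def _superpose_chain(
    mobile_model: StructureModel,
    mobile_chain: str,
    target_model: StructureModel,
    target_chain: str,
) -> StructureModel:
    """Rigidly fit one chain onto another by the Cα of their common residues."""
    import numpy as np

    from .site_mapping import kabsch_superpose

    target_by_num = {r.number: r for r in target_model.chain(target_chain) if r.has_atom("CA")}
    mobile, target = [], []
    for res in mobile_model.chain(mobile_chain):
        other = target_by_num.get(res.number)
        if other is not None and res.has_atom("CA"):
            mobile.append(res.atom("CA").xyz)
            target.append(other.atom("CA").xyz)
    if len(mobile) < 3:
        raise ValueError(
            f"chains {mobile_chain!r}/{target_chain!r} share fewer than 3 Cα residues"
        )
    sup = kabsch_superpose(np.array(mobile), np.array(target))
    return mobile_model.transformed(sup.rotation, sup.translation)


def _merge_models(
    model_a: StructureModel, chain_a: str, model_b: StructureModel, chain_b: str
) -> StructureModel:
    """Composite model holding one chain from each source (for persistence checks)."""
    return StructureModel(
        identifier=f"{model_a.identifier}+{model_b.identifier}",
        chains={chain_a: model_a.chains[chain_a], chain_b: model_b.chains[chain_b]},
    )


RECIPES: dict[str, tuple[Callable[[_Run], RecipeReport], dict[str, str]]] = {
    "fig3_contacts": (_fig3_contacts, {"1F8H": "EH2–STNPFR complex"}),
    "fig5_compare": (_fig5_compare, {"1F8H": "EH2–STNPFR complex", "1FF1": "EH2–STNPFL complex"}),
    "fig6_overlap": (_fig6_overlap, {"3DQB": "rhodopsin–Gα-peptide", "1F8H": "EH2–STNPFR complex"}),
    "fig7_distance": (_fig7_distance, {"6QNO": "rhodopsin–Gi complex"}),
    "fig8_ctail": (_fig8_ctail, {"1U19": "ground-state rhodopsin"}),
    "fig9_dimer": (_fig9_dimer, {"6OFJ": "rhodopsin dimer"}),
    "fig10_states": (_fig10_states, {"6QNO": "rhodopsin–Gi complex", "1A0R": "phosducin–Gβγ"}),
}


def run_recipe(config: RecipeConfig) -> RecipeReport:
    """Run a named recipe; writes tables to ``config.output_dir`` when set."""
    try:
        func, required = RECIPES[config.recipe]
    except KeyError:
        raise KeyError(
            f"unknown recipe {config.recipe!r}; available: {sorted(RECIPES)}"
        ) from None
    run = _Run(config, required)
    report = func(run)
    if config.output_dir:
        report.write(config.output_dir)
    return report
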