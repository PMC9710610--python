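"""Run configuration: one YAML/JSON document driving the whole pipeline.

Unknown keys are rejected with a listing, every default is overridable,
and the resolved configuration (including the seed) is echoed alongside
outputs for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import SimulationParams
from .germline import (
    GermlineReference,
    JunctionModel,
    RecombinationSettings,
    UsageDistribution,
    load_default_reference,
    load_reference,
)
from .shm import ShmModel, load_fivemer_tsv

_TOP_KEYS = {
    "seed", "receptor", "reference_fasta", "productive_only",
    "dynamics", "shm", "selection", "junction", "usage",
    "transcriptome", "spatial",
}
_DYNAMICS_KEYS = {
    "n_steps", "init_clones", "p_new_clone", "p_div0", "beta_div", "p_death",
    "p_max", "isotype_T", "phenotype_T", "phenotype_T_selected", "phenotypes",
    "initial_phenotype", "shm_prob_by_isotype", "shm_prob_by_phenotype",
    "shm_prob_default",
}
_SHM_KEYS = {"model", "lambda", "kappa", "region_weights", "fivemer_tsv"}
_SELECTION_KEYS = {"mode", "param", "step", "multiplier"}
_JUNCTION_KEYS = {"ins_len_dist", "del_len_dist", "ins_base_dist"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {unknown}")


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top level")
    for section, keys in (
        ("dynamics", _DYNAMICS_KEYS),
        ("shm", _SHM_KEYS),
        ("selection", _SELECTION_KEYS),
    ):
        if section in doc and doc[section] is not None:
            _check_keys(doc[section], keys, section)
    return doc


def build_run(
    config: dict, seed: int | None = None
) -> tuple[SimulationParams, ShmModel, RecombinationSettings]:
    """Resolve a config document into the three run objects."""
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)

    reference: GermlineReference
    if config.get("reference_fasta"):
        reference = load_reference(config["reference_fasta"])
    else:
        reference = load_default_reference()

    receptor = config.get("receptor", "B")
    junction_cfg = config.get("junction") or {}
    _check_keys(junction_cfg, _JUNCTION_KEYS, "junction")
    junction = (
        JunctionModel(**{k: np.asarray(v, dtype=float) for k, v in junction_cfg.items()})
        if junction_cfg
        else JunctionModel()
    )
    usage_cfg = config.get("usage") or {}
    settings = RecombinationSettings(
        reference=reference,
        receptor=receptor,
        productive_only=bool(config.get("productive_only", True)),
        heavy_junction=junction,
        light_junction=junction,
    )
    for which in ("heavy", "light"):
        if which in usage_cfg:
            locus = getattr(settings, f"{which}_usage").locus
            u = UsageDistribution(locus=locus, weights=usage_cfg[which])
            u.validate(reference)
            setattr(settings, f"{which}_usage", u)

    dyn = dict(config.get("dynamics") or {})
    sel = dict(config.get("selection") or {})
    params = SimulationParams(
        seed=int(config.get("seed", 0)),
        selection_mode=sel.get("mode", "none"),
        selection_param=sel.get("param"),
        selection_step=int(sel.get("step", 0)),
        sel_multiplier=float(sel.get("multiplier", 1.0)),
        **{
            k: (np.asarray(v, dtype=float) if k.endswith("_T") or k == "phenotype_T_selected" else v)
            for k, v in dyn.items()
        },
    )

    shm_cfg = dict(config.get("shm") or {})
    fivemer = None
    if shm_cfg.get("fivemer_tsv"):
        fivemer = load_fivemer_tsv(shm_cfg["fivemer_tsv"])
    shm_model = ShmModel(
        name=shm_cfg.get("model", "poisson"),
        lam=float(shm_cfg.get("lambda", 5.0)),
        kappa=float(shm_cfg.get("kappa", 3.0)),
        region_weights=[tuple(r) for r in shm_cfg.get("region_weights", [])],
        fivemer_table=fivemer,
    )
    return params, shm_model, settings


def resolved_config(params: SimulationParams, shm_model: ShmModel, settings) -> dict:
    """A JSON/YAML-serializable echo of the effective configuration."""
    return {
        "seed": params.seed,
        "receptor": settings.receptor,
        "productive_only": settings.productive_only,
        "dynamics": {
            "n_steps": params.n_steps,
            "init_clones": params.init_clones,
            "p_new_clone": params.p_new_clone,
            "p_div0": params.p_div0,
            "beta_div": params.beta_div,
            "p_death": params.p_death,
            "p_max": params.p_max,
            "shm_prob_default": params.shm_prob_default,
            "isotype_T": params.isotype_T.tolist(),
            "phenotype_T": params.phenotype_T.tolist(),
            "phenotypes": list(params.phenotypes),
        },
        "selection": {
            "mode": params.selection_mode,
            "param": params.selection_param,
            "step": params.selection_step,
            "multiplier": params.sel_multiplier,
        },
        "shm": {"model": shm_model.name, "lambda": shm_model.lam, "kappa": shm_model.kappa},
    }
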