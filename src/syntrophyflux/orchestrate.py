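"""End-to-end orchestration of the analysis chain.

``run_all`` wires the stages together — protein quantification, isotope
partitioning, ammonia speciation, community FBA under both partner
scenarios, and the thermodynamic H2 sweep — and writes a single versioned,
machine-readable summary.  Inputs may be real TSV tables or the synthetic
generators; one top-level seed is fanned out deterministically to every
random stage, so reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from . import isotopes, quant, synth, thermo
from .ammonia import AmmoniaConditions
from .ammonia import free_ammonia as _free_ammonia
from .fba import (
    apply_proteome_atp_constraints,
    community_yield,
    pfba,
    scenario_drop_guild,
)
from .network import load_model

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

__all__ = ["run_all", "validate_config"]


def validate_config(config: dict) -> dict:
    """Fill defaults and fail fast on missing inputs before any computation."""
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("model", "community")
    cfg.setdefault("proteomics", {"synthetic": {}})
    cfg.setdefault("headspace", {"synthetic": {}})
    cfg.setdefault("ammonia", {"tan": 1.6, "ph": 8.0, "temperature": 328.15})
    cfg.setdefault("proteome_shares", dict(_fixture_shares()))
    cfg.setdefault("drop_guild", "m2")
    cfg.setdefault("thermo", {})
    for stage in ("proteomics", "headspace"):
        block = cfg[stage]
        if "synthetic" not in block:
            for key, path in block.items():
                if key == "unit":
                    continue
                if not Path(path).exists():
                    raise FileNotFoundError(f"{stage}: input file {path!r} not found")
    if isinstance(cfg["model"], str) and cfg["model"] not in ("community",):
        if not Path(cfg["model"]).exists():
            raise FileNotFoundError(f"model path {cfg['model']!r} not found")
    return cfg


def _fixture_shares():
    from .fixture import PROTEOME_SHARES

    return PROTEOME_SHARES


def _stage(name):
    logger.info("stage: %s", name)


def run_all(config: dict, out_dir) -> dict:
    """Execute the full chain; returns (and writes) the summary dict."""
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }

    try:
        _stage("quant")
        summary["quant"] = _run_quant(cfg, seed, out_dir)
        _stage("partition")
        summary["partition"] = _run_partition(cfg, seed)
        _stage("ammonia")
        summary["ammonia"] = _run_ammonia(cfg)
        _stage("fba")
        fba_a, fba_b, yields = _run_fba(cfg)
        summary["fba"] = fba_a
        summary["fba_dropped"] = fba_b
        _stage("thermo")
        summary["thermo"] = _run_thermo(cfg, yields)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        summary["failed"] = True
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        raise RuntimeError(f"pipeline aborted during a stage: {exc}") from exc

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _run_quant(cfg, seed, out_dir):
    block = cfg["proteomics"]
    if "synthetic" in block:
        overrides = dict(block["synthetic"])
        overrides.setdefault("seed", seed)
        design = synth.CommunityDesign(**overrides)
        tables = synth.simulate_proteomics(design, out_dir=out_dir / "synthetic_proteomics")
        proteins, lfq, labels, samples = (
            tables["proteins"], tables["lfq"], tables["labels"], tables["samples"],
        )
        acetate_dose = design.acetate_dose_mg_per_l
    else:
        proteins = quant.read_proteins(block["proteins"])
        lfq = quant.read_lfq(block["lfq"])
        labels = quant.read_labels(block["labels"], unit=block.get("unit"))
        samples = quant.read_samples(block["samples"])
        acetate_dose = float(block.get("acetate_dose_mg_per_l", 3000.0))

    per_protein, per_mag = quant.quantify_all_samples(proteins, lfq, labels, samples)
    per_protein.to_csv(out_dir / "protein_quant.tsv", sep="\t", index=False)
    per_mag.to_csv(out_dir / "mag_label_summary.tsv", sep="\t", index=False)

    final_t = per_mag["time_h"].max()
    final = per_mag[per_mag["time_h"] == final_t]
    c13_by_mag = final.groupby("mag_id")["c13_protein_mg_per_l"].mean()
    y_vss, y_cod = quant.biomass_yield(float(c13_by_mag.sum()), acetate_dose)
    frac = final.groupby("mag_id")["metaproteome_fraction"].mean()
    return {
        "final_time_h": float(final_t),
        "c13_protein_mg_per_l": c13_by_mag.to_dict(),
        "metaproteome_fraction": frac.to_dict(),
        "biomass_yield_g_vss_per_g_acetate": y_vss,
        "biomass_yield_g_cod_per_g_cod": y_cod,
    }


def _run_partition(cfg, seed):
    block = cfg["headspace"]
    if "synthetic" in block:
        overrides = dict(block["synthetic"])
        overrides.setdefault("seed", seed + 1)
        overrides.setdefault("f_sao", 0.98)
        overrides.setdefault("noise", 0.02)
        sim = synth.simulate_headspace(**overrides)
        obs = [
            isotopes.HeadspaceObservation(
                time_h=r.time_h, a_co2=r.a_co2, a_ch4=r.a_ch4,
                a_methyl=r.a_methyl, a_dic_background=r.a_dic_background,
            )
            for r in sim["observations"].itertuples(index=False)
        ]
    else:
        obs = isotopes.read_headspace(block["path"], unit=block.get("unit", "fraction"))
    res = isotopes.estimate_sao_fraction_series(obs)
    res.pop("estimates")
    return res


def _run_ammonia(cfg):
    block = dict(cfg["ammonia"])
    if "temperature_c" in block:
        block["temperature"] = float(block.pop("temperature_c")) + 273.15
    cond = AmmoniaConditions(
        tan=float(block["tan"]), ph=float(block["ph"]),
        temperature=float(block.get("temperature", 328.15)),
    )
    return {
        "tan_g_per_l": cond.tan,
        "ph": cond.ph,
        "temperature_k": cond.temperature,
        "free_ammonia_g_n_per_l": _free_ammonia(cond),
    }


def _run_fba(cfg):
    model = load_model(cfg["model"])
    model = apply_proteome_atp_constraints(model, cfg["proteome_shares"])
    sol_a = pfba(model)
    if not sol_a.ok:
        raise RuntimeError(f"community pFBA failed: {sol_a.status}")
    yield_a = community_yield(sol_a)

    dropped = scenario_drop_guild(model, cfg["drop_guild"])
    sol_b = pfba(dropped)
    yield_b = community_yield(sol_b) if sol_b.ok else {"status": sol_b.status}
    return yield_a, yield_b, (yield_a, yield_b if sol_b.ok else None)


def _run_thermo(cfg, yields):
    block = dict(cfg["thermo"])
    table = thermo.load_thermo_table(block.get("table"))
    cond = thermo.Conditions(
        temperature=float(block.get("temperature", 328.15)),
        ph=float(block.get("ph", 7.0)),
        concentrations=block.get("concentrations", thermo.Conditions().concentrations),
    )
    yield_a, yield_b = yields
    out = {}
    community_rxn = {"acetate": -1.0, "h": -1.0, "ch4": 1.0, "co2": 1.0}
    std = thermo.Conditions(
        temperature=298.15, ph=7.0,
        concentrations={k: 1.0 for k in ("acetate", "formate", "ch4", "co2", "h2")},
    )
    out["community_dg_standard_transformed_kj"] = thermo.delta_g_insitu(
        community_rxn, table, std
    )
    out["community_dg_per_atp_kj"] = thermo.dg_per_atp(
        out["community_dg_standard_transformed_kj"], yield_a["atp_total"]
    )
    sweep_a = thermo.h2_sweep(yield_a, table, cond, scenario="with_partner")
    win_a = thermo.syntrophy_window(sweep_a)
    out["window_with_partner_atm"] = list(win_a) if win_a else None
    if yield_b is not None:
        sweep_b = thermo.h2_sweep(yield_b, table, cond, scenario="without_partner")
        win_b = thermo.syntrophy_window(
            sweep_b, consumers=tuple(g for g in yield_b["atp_per_guild"] if g != "saob")
        )
        out["window_without_partner_atm"] = list(win_b) if win_b else None
    return out
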