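"""End-to-end pipeline chaining all mapping stages.

A single configuration (dict or YAML) drives: simulation (or loading a
dosage table), filtering, two-point screening, grouping, MDS ordering,
HMM phasing and map estimation, haplotype reconstruction and meiotic
diagnostics.  Every stage writes its artifacts to the output directory
and later stages reload them, so a run is resumable per stage and
byte-reproducible given the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from polymap import simulate as sim
from polymap.diagnostics import (
    build_chains,
    detect_crossovers,
    pairing_posterior,
    valency_summary,
)
from polymap.grouping import mds_order, upgma_groups
from polymap.haplotypes import genotype_posteriors, gic, homolog_probabilities
from polymap.hmm import EmissionModel, PhasedMap, phase_markers, reestimate_rfs
from polymap.io import DosageTable, read_dosage_csv, write_dosage_csv
from polymap.twopoint import rf_matrix

log = logging.getLogger("polymap")

DEFAULT_CONFIG = {
    "ploidy": 6,
    "seed": 1,
    "n_groups": 1,
    "emission": {"mode": "dosage", "eps": 0.0},
    "filters": {"min_posterior": 0.8, "max_missing": 0.25, "seg_alpha": 5e-4},
    "stages": ["simulate", "filter", "twopoint", "group", "order", "build",
               "haplotype", "meiosis"],
    "simulate": {
        "n_markers": 30,
        "map_length_cM": 60.0,
        "n_ind": 200,
        "error_rate": 0.0,
        "missing_rate": 0.0,
        "posterior_sharpness": 5.0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _require(path: Path, stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires missing artifact {path.name}; "
            f"run its producing stage first"
        )


def serialize_map(pm: PhasedMap, table: DosageTable, path: Path, sidecar: Path, settings: dict):
    pos = pm.positions_cM
    rows = []
    for t in range(pm.n_markers):
        di = int(pm.markers[t])
        rows.append(
            {
                "marker": table.marker_ids[di],
                "position_cM": pos[t],
                "dosage_P": int(table.dP[di]),
                "dosage_Q": int(table.dQ[di]),
                "phase_P": "".join(map(str, pm.phase_P[t])),
                "phase_Q": "".join(map(str, pm.phase_Q[t])),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar.write_text(
        json.dumps(
            {
                "loglik": pm.loglik,
                "length_cM": pm.length_cM,
                "n_markers": pm.n_markers,
                "dropped": [table.marker_ids[i] for i in pm.dropped],
                "settings": settings,
            },
            indent=2,
        )
    )


def load_map(path: Path, table: DosageTable) -> PhasedMap:
    df = pd.read_csv(path, dtype={"phase_P": str, "phase_Q": str})
    idx = {mk: i for i, mk in enumerate(table.marker_ids)}
    markers = np.array([idx[mk] for mk in df["marker"]])
    phase_P = np.array([[int(c) for c in s] for s in df["phase_P"]], dtype=np.int8)
    phase_Q = np.array([[int(c) for c in s] for s in df["phase_Q"]], dtype=np.int8)
    pos = df["position_cM"].to_numpy()
    rf = 0.5 * (1.0 - np.exp(-np.diff(pos) / 50.0))
    return PhasedMap(markers, phase_P, phase_Q, np.clip(rf, 1e-6, 0.4999))


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; returns a dict of artifact paths."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m = cfg["ploidy"]
    seed = int(cfg["seed"])
    emission = EmissionModel(**cfg["emission"])
    stages = cfg["stages"]
    artifacts: dict[str, Path] = {}

    dosage_csv = out / "dosage.csv"
    posterior_csv = out / "posteriors.csv"
    filtered_csv = out / "dosage_filtered.csv"
    filtered_post = out / "posteriors_filtered.csv"

    if "simulate" in stages:
        s = cfg["simulate"]
        rng = np.random.default_rng(seed)
        parents = sim.simulate_parents(
            m, s["n_markers"], s["map_length_cM"], seed=rng
        )
        truth = sim.simulate_population(parents, s["n_ind"], seed=rng)
        obs = sim.observe_dosages(
            truth,
            error_rate=s["error_rate"],
            missing_rate=s["missing_rate"],
            posterior_sharpness=s["posterior_sharpness"],
            seed=rng,
        )
        table = DosageTable.from_observed(obs)
        write_dosage_csv(table, dosage_csv, posterior_csv)
        truth_rows = []
        for i, (mp, mq) in enumerate(zip(truth.meioses_P, truth.meioses_Q)):
            for parent, rec in (("P", mp), ("Q", mq)):
                for c in range(rec.sources.shape[0]):
                    for t in range(rec.sources.shape[1]):
                        truth_rows.append(
                            (f"Ind{i+1}", f"M{t+1}", parent, c, int(rec.sources[c, t]))
                        )
        pd.DataFrame(
            truth_rows,
            columns=["individual", "marker", "parent", "chromatid", "source_homolog"],
        ).to_csv(out / "truth_sources.tsv", sep="\t", index=False)
        artifacts["dosage"] = dosage_csv
        log.info("simulate: %d markers x %d individuals", s["n_markers"], s["n_ind"])

    if "filter" in stages:
        _require(dosage_csv, "filter")
        from polymap.io import apply_filters

        table = read_dosage_csv(
            dosage_csv, m, posterior_csv if posterior_csv.exists() else None
        )
        table, report = apply_filters(table, **cfg["filters"])
        write_dosage_csv(table, filtered_csv, filtered_post)
        (out / "filter_report.json").write_text(json.dumps(report, indent=2))
        artifacts["filtered"] = filtered_csv
        log.info("filter: %s", report)

    def _load_filtered() -> DosageTable:
        _require(filtered_csv, "downstream")
        return read_dosage_csv(
            filtered_csv, m, filtered_post if filtered_post.exists() else None
        )

    if "twopoint" in stages:
        table = _load_filtered()
        rf, lod, _ = rf_matrix(table)
        np.savetxt(out / "rf_matrix.csv", rf, delimiter=",")
        np.savetxt(out / "lod_matrix.csv", lod, delimiter=",")
        artifacts["rf_matrix"] = out / "rf_matrix.csv"

    if "group" in stages:
        table = _load_filtered()
        _require(out / "rf_matrix.csv", "group")
        rf = np.loadtxt(out / "rf_matrix.csv", delimiter=",", ndmin=2)
        groups = upgma_groups(rf, int(cfg["n_groups"]))
        pd.DataFrame({"marker": table.marker_ids, "group": groups}).to_csv(
            out / "groups.csv", index=False
        )
        artifacts["groups"] = out / "groups.csv"

    if "order" in stages:
        table = _load_filtered()
        _require(out / "groups.csv", "order")
        rf = np.loadtxt(out / "rf_matrix.csv", delimiter=",", ndmin=2)
        lod = np.loadtxt(out / "lod_matrix.csv", delimiter=",", ndmin=2)
        groups = pd.read_csv(out / "groups.csv")["group"].to_numpy()
        rows = []
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            if len(idx) < 3:
                order_local = idx
                positions = np.arange(len(idx), dtype=float)
            else:
                res = mds_order(rf[np.ix_(idx, idx)], lod[np.ix_(idx, idx)])
                order_local = idx[res.order]
                positions = np.sort(res.positions)
            for rank, (mi, p) in enumerate(zip(order_local, positions)):
                rows.append((table.marker_ids[mi], int(g), rank, float(p)))
        pd.DataFrame(
            rows, columns=["marker", "group", "rank", "mds_position"]
        ).to_csv(out / "orders.csv", index=False)
        artifacts["orders"] = out / "orders.csv"

    if "build" in stages:
        table = _load_filtered()
        _require(out / "orders.csv", "build")
        orders = pd.read_csv(out / "orders.csv")
        idx = {mk: i for i, mk in enumerate(table.marker_ids)}
        maps = []
        for g, grp in orders.groupby("group"):
            order = [idx[mk] for mk in grp.sort_values("rank")["marker"]]
            pm = phase_markers(order, table, emission=emission)
            pm = reestimate_rfs(pm, table, emission)
            maps.append((g, pm))
        for g, pm in maps:
            serialize_map(
                pm, table, out / f"map_group{g}.csv", out / f"map_group{g}.json",
                {"emission": cfg["emission"], "seed": seed},
            )
        artifacts["maps"] = [out / f"map_group{g}.csv" for g, _ in maps]

    if "haplotype" in stages or "meiosis" in stages:
        table = _load_filtered()
        map_files = sorted(out.glob("map_group*.csv"))
        if not map_files:
            raise FileNotFoundError("haplotype/meiosis stages require map_group*.csv")
        for map_file in map_files:
            tag = map_file.stem.replace("map_", "")
            pm = load_map(map_file, table)
            post = genotype_posteriors(pm, table, emission)
            prof = homolog_probabilities(post, pm)
            if "haplotype" in stages:
                gP, gQ = gic(prof)
                rows = []
                z, n, mm = prof.prob_P.shape
                for parent, prob in (("P", prof.prob_P), ("Q", prof.prob_Q)):
                    for t in range(z):
                        for h in range(mm):
                            rows.append(
                                {
                                    "parent": parent,
                                    "marker": table.marker_ids[pm.markers[t]],
                                    "position_cM": prof.positions_cM[t],
                                    "homolog": h,
                                    "mean_probability": float(prob[t, :, h].mean()),
                                    "gic": float((gP if parent == "P" else gQ)[t, h]),
                                }
                            )
                pd.DataFrame(rows).to_csv(out / f"haplotypes_{tag}.csv", index=False)
                artifacts.setdefault("haplotypes", []).append(out / f"haplotypes_{tag}.csv")
            if "meiosis" in stages:
                calls, conclusive = detect_crossovers(prof, pm, table, emission)
                calls.to_csv(out / f"crossovers_{tag}.csv", index=False)
                chains = build_chains(calls, table.m)
                valency_summary(chains, conclusive).to_csv(
                    out / f"valency_{tag}.csv", index=False
                )
                for parent in "PQ":
                    pp = pairing_posterior(post, pm, parent)
                    df = pd.DataFrame(
                        pp.pair_profile,
                        columns=["-".join(p) for p in pp.pair_labels],
                    )
                    df.insert(0, "position_cM", pp.positions_cM)
                    df["chi2_p_configs"] = pp.config_p
                    df.to_csv(out / f"pairing_{tag}_{parent}.csv", index=False)
                artifacts.setdefault("meiosis", []).append(out / f"crossovers_{tag}.csv")

    return artifacts
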