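"""Dosage-table I/O, VCF import and the marker filtering pipeline.

The canonical interchange format is a dosage-table CSV: one row per
marker with its identifier, optional genomic anchor (chromosome,
1-based bp), the two parental dosages and one column per offspring
individual holding the called dosage (``NA`` for missing).  Caller
posterior vectors travel in a companion long-format CSV.  VCF input is
converted to the same table (biallelic SNPs only; a dosage FORMAT
field is preferred over GT when present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from polymap.core import _as_m, expected_segregation

__all__ = ["DosageTable", "read_vcf", "read_dosage_csv", "write_dosage_csv", "apply_filters"]


@dataclass
class DosageTable:
    """In-memory dosage table for a full-sib population.

    Satisfies the observation interface consumed by the two-point and
    HMM machinery (``m``, ``dP``, ``dQ``, ``dosage``, ``posterior``).
    """

    m: int
    marker_ids: list[str]
    dP: np.ndarray  # (z,)
    dQ: np.ndarray
    dosage: np.ndarray  # (z, n) float, nan = missing
    individuals: list[str]
    posterior: np.ndarray | None = None  # (z, n, m+1)
    chrom: list[str] | None = None
    pos_bp: np.ndarray | None = None  # 1-based, VCF convention
    positions_cM: np.ndarray | None = None
    depth: np.ndarray | None = None  # (z,) mean read depth, optional

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, idx) -> "DosageTable":
        idx = np.asarray(idx)
        return DosageTable(
            m=self.m,
            marker_ids=[self.marker_ids[i] for i in idx],
            dP=self.dP[idx],
            dQ=self.dQ[idx],
            dosage=self.dosage[idx],
            individuals=list(self.individuals),
            posterior=None if self.posterior is None else self.posterior[idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            pos_bp=None if self.pos_bp is None else self.pos_bp[idx],
            positions_cM=None if self.positions_cM is None else self.positions_cM[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    @classmethod
    def from_observed(cls, obs, marker_ids=None, individuals=None) -> "DosageTable":
        """Wrap an ObservedData object from the simulator."""
        z, n = obs.dosage.shape
        return cls(
            m=obs.m,
            marker_ids=marker_ids or (obs.marker_ids or [f"M{t+1}" for t in range(z)]),
            dP=np.asarray(obs.dP),
            dQ=np.asarray(obs.dQ),
            dosage=obs.dosage,
            individuals=individuals or [f"Ind{i+1}" for i in range(n)],
            posterior=obs.posterior,
            positions_cM=getattr(obs, "positions_cM", None),
        )


def write_dosage_csv(table: DosageTable, path, posterior_path=None) -> None:
    df = pd.DataFrame(
        {
            "marker": table.marker_ids,
            "chrom": table.chrom if table.chrom is not None else ["."] * table.n_markers,
            "pos_bp": table.pos_bp if table.pos_bp is not None else [0] * table.n_markers,
            "dP": table.dP,
            "dQ": table.dQ,
        }
    )
    dos = pd.DataFrame(table.dosage, columns=table.individuals)
    out = pd.concat([df, dos], axis=1)
    out.to_csv(path, index=False, na_rep="NA")
    if posterior_path is not None and table.posterior is not None:
        z, n, c = table.posterior.shape
        rows = table.posterior.reshape(z * n, c)
        long = pd.DataFrame(rows, columns=[f"p{d}" for d in range(c)])
        long.insert(0, "individual", np.tile(table.individuals, z))
        long.insert(0, "marker", np.repeat(table.marker_ids, n))
        long.to_csv(posterior_path, index=False)


def read_dosage_csv(path, ploidy, posterior_path=None) -> DosageTable:
    m = _as_m(ploidy)
    df = pd.read_csv(path, na_values=["NA"])
    meta = ["marker", "chrom", "pos_bp", "dP", "dQ"]
    individuals = [c for c in df.columns if c not in meta]
    table = DosageTable(
        m=m,
        marker_ids=[str(x) for x in df["marker"]],
        dP=df["dP"].to_numpy(dtype=np.int64),
        dQ=df["dQ"].to_numpy(dtype=np.int64),
        dosage=df[individuals].to_numpy(dtype=float),
        individuals=individuals,
        chrom=[str(x) for x in df["chrom"]] if "chrom" in df else None,
        pos_bp=df["pos_bp"].to_numpy() if "pos_bp" in df else None,
    )
    if posterior_path is not None:
        long = pd.read_csv(posterior_path)
        pcols = [c for c in long.columns if c.startswith("p")]
        z, n = table.n_markers, table.n_individuals
        post = np.full((z, n, m + 1), 1.0 / (m + 1))
        midx = {mk: i for i, mk in enumerate(table.marker_ids)}
        iidx = {ind: i for i, ind in enumerate(individuals)}
        ti = long["marker"].astype(str).map(midx).to_numpy()
        ii = long["individual"].astype(str).map(iidx).to_numpy()
        post[ti, ii] = long[pcols].to_numpy()
        table.posterior = post
    return table


def read_vcf(path, ploidy, parent_P: str, parent_Q: str, dosage_field: str = "DS") -> DosageTable:
    """Convert a VCF to a dosage table.

    Keeps biallelic SNPs only (multi-allelic records are skipped and
    counted); genotype dosage is the alternative-allele count in GT,
    unless ``dosage_field`` is present, which takes precedence.
    Records whose GT ploidy differs from ``m`` are skipped.
    """
    from cyvcf2 import VCF

    m = _as_m(ploidy)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in (parent_P, parent_Q):
        if p not in samples:
            raise ValueError(f"parent sample {p!r} not found in VCF")
    off = [s for s in samples if s not in (parent_P, parent_Q)]
    iP, iQ = samples.index(parent_P), samples.index(parent_Q)
    i_off = [samples.index(s) for s in off]

    ids, chroms, pos, dPs, dQs, rows = [], [], [], [], [], []
    skipped_multiallelic = 0
    skipped_ploidy = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped_multiallelic += 1
            continue
        try:
            ds = var.format(dosage_field)
        except Exception:
            ds = None
        if ds is not None:
            vals = ds[:, 0].astype(float)
            vals[vals < 0] = np.nan
        else:
            gts = var.genotypes  # [a1..am, phased]
            vals = np.full(len(samples), np.nan)
            bad_ploidy = False
            for si, g in enumerate(gts):
                alleles = g[:-1]
                if len(alleles) != m:
                    bad_ploidy = True
                    break
                if any(a < 0 for a in alleles):
                    continue
                vals[si] = float(sum(1 for a in alleles if a > 0))
            if bad_ploidy:
                skipped_ploidy += 1
                continue
        if np.isnan(vals[iP]) or np.isnan(vals[iQ]):
            continue
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        dPs.append(int(vals[iP]))
        dQs.append(int(vals[iQ]))
        rows.append(vals[i_off])
    table = DosageTable(
        m=m,
        marker_ids=ids,
        dP=np.array(dPs, dtype=np.int64),
        dQ=np.array(dQs, dtype=np.int64),
        dosage=np.array(rows, dtype=float) if rows else np.empty((0, len(off))),
        individuals=off,
        chrom=chroms,
        pos_bp=np.array(pos, dtype=np.int64),
    )
    table.import_report = {  # type: ignore[attr-defined]
        "skipped_multiallelic": skipped_multiallelic,
        "skipped_ploidy_mismatch": skipped_ploidy,
    }
    return table


def _segregation_pvalue(m: int, dP: int, dQ: int, obs: np.ndarray) -> float:
    """Chi-square P of the observed dosage counts vs the polysomic expectation."""
    exp = expected_segregation(dP, dQ, m)
    counts = np.zeros(m + 1)
    vals, cnt = np.unique(obs[~np.isnan(obs)].astype(np.int64), return_counts=True)
    counts[vals] = cnt
    n = counts.sum()
    if n == 0:
        return 1.0
    # pool classes with tiny expectation into their neighbors
    keep = exp > 1e-12
    e = exp[keep] * n
    o = counts[keep]
    if (counts[~keep] > 0).any():
        return 0.0  # offspring in an impossible class
    order = np.argsort(e)
    while len(e) > 2 and e[order[0]] < 1.0:
        i = order[0]
        j = order[1] if order[1] != i else order[2]
        e[j] += e[i]
        o[j] += o[i]
        e = np.delete(e, i)
        o = np.delete(o, i)
        order = np.argsort(e)
    if len(e) < 2:
        return 1.0
    stat, p = chisquare(o, e * (o.sum() / e.sum()))
    return float(p)


def apply_filters(
    table: DosageTable,
    min_posterior: float = 0.8,
    max_missing: float = 0.25,
    seg_alpha: float = 5e-4,
    min_depth: float = 20.0,
) -> tuple[DosageTable, dict]:
    """Quality filters applied in fixed order; returns (table, report).

    1. cells whose top posterior is below ``min_posterior`` become missing;
    2. markers with more than ``max_missing`` missing data are removed;
    3. markers failing the segregation chi-square against the polysomic
       expectation at ``P < seg_alpha`` are removed;
    4. when read depth is available, markers below ``min_depth`` are removed.
    """
    m = table.m
    t = table.subset_markers(np.arange(table.n_markers))
    report = {"input_markers": t.n_markers}

    if t.posterior is not None:
        low = t.posterior.max(axis=2) < min_posterior
        t.dosage = t.dosage.copy()
        t.dosage[low] = np.nan
        report["cells_set_missing"] = int(low.sum())

    miss = np.isnan(t.dosage).mean(axis=1)
    keep = miss <= max_missing
    report["removed_missingness"] = int((~keep).sum())
    t = t.subset_markers(np.where(keep)[0])

    pvals = np.array(
        [
            _segregation_pvalue(m, int(t.dP[i]), int(t.dQ[i]), t.dosage[i])
            for i in range(t.n_markers)
        ]
    )
    keep = pvals >= seg_alpha
    report["removed_segregation"] = int((~keep).sum())
    t = t.subset_markers(np.where(keep)[0])

    if t.depth is not None:
        keep = t.depth >= min_depth
        report["removed_depth"] = int((~keep).sum())
        t = t.subset_markers(np.where(keep)[0])
    else:
        report["removed_depth"] = 0

    report["output_markers"] = t.n_markers
    return t, report
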