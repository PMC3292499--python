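"""Reading and writing trio data and results.

Input is PLINK-style text PED/MAP.  Each family must form a
father-mother-child trio with an affected child (phenotype 2); genotypes
are recoded to copies of a designated risk allele (default: the minor
allele per locus).  Trios with missing genotypes or Mendelian
inconsistencies at a locus are excluded at that locus and counted.

Outputs are plain TSV tables (per-locus statistics; per-trio-type
posteriors) plus a JSON sidecar recording the settings needed to reproduce
a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .em_mixture import FitResult, TrioCounts, linked_decision
from .genetic_model import TRIO_INDEX, TRIO_LABELS

__all__ = [
    "TrioDataset",
    "read_ped",
    "write_ped",
    "counts_by_type",
    "write_results",
]

logger = logging.getLogger(__name__)

MISSING = -1

RESULT_COLUMNS = [
    "chrom", "locus", "bp", "tdt_het", "p_perm", "t_hat", "pi1_hat",
    "sumstat", "sumstat_p", "tdt", "tdt_p_perm", "odds_ratio", "maxT_p",
]


@dataclass
class TrioDataset:
    """Coded trios at one or more loci.

    ``codes[j, l]`` is the canonical trio-type index (0..9) of family j at
    locus l, or -1 if the trio is excluded there (missing genotype or
    Mendelian error).  ``loci`` carries marker metadata; ``excluded``
    counts exclusions per locus by reason.
    """

    codes: np.ndarray
    families: list[str]
    loci: pd.DataFrame
    excluded: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_trios(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]


def counts_by_type(data: TrioDataset, locus: int) -> TrioCounts:
    """Ten-cell trio-type counts at one locus (excluded trios dropped)."""
    codes = data.codes[:, locus]
    return TrioCounts(np.bincount(codes[codes >= 0], minlength=10))


def _read_map(map_path) -> pd.DataFrame:
    loci = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": str, "id": str},
    )
    if loci["id"].duplicated().any():
        raise ValueError("duplicate marker ids in MAP file")
    return loci


def _risk_allele_for_locus(alleles: np.ndarray, policy: str) -> str:
    """Pick the tracked allele M: 'minor' or 'named:<allele>'."""
    observed = alleles[alleles != "0"]
    uniq, counts = np.unique(observed, return_counts=True)
    if uniq.size > 2:
        raise ValueError(f"more than two alleles observed: {list(uniq)}")
    if policy.startswith("named:"):
        name = policy.split(":", 1)[1]
        return name
    if uniq.size == 0:
        return "0"
    # minor allele; deterministic tie-break by allele name
    order = np.lexsort((uniq, counts))
    return str(uniq[order[0]])


def read_ped(ped_path, map_path, risk_allele: str = "minor") -> TrioDataset:
    """Assemble coded trios from PLINK text PED/MAP files.

    PED columns: FID, IID, PAT, MAT, SEX, PHENO, then two allele columns
    per locus.  A family is used when it contains exactly one affected
    child (PHENO = 2) whose two parents are present; other family
    structures are skipped with a warning.  ``risk_allele`` is ``"minor"``
    or ``"named:<allele>"`` applied to every locus.
    """
    loci = _read_map(map_path)
    n_loci = len(loci)
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"PED row for {parts[:2]} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_loci}"
                )
            rows.append(parts)
    if not rows:
        raise ValueError("empty PED file")
    ped = pd.DataFrame(rows)
    meta = ped.iloc[:, :6].to_numpy(dtype=str)
    geno = ped.iloc[:, 6:].to_numpy(dtype=str).reshape(len(ped), n_loci, 2)

    # resolve one risk allele per locus over all individuals
    risk = np.array(
        [
            _risk_allele_for_locus(geno[:, locus, :].ravel(), risk_allele)
            for locus in range(n_loci)
        ]
    )

    by_family: dict[str, list[int]] = {}
    for i, fid in enumerate(meta[:, 0]):
        by_family.setdefault(fid, []).append(i)

    trio_rows = []  # (fid, father_idx, mother_idx, child_idx)
    for fid, members in by_family.items():
        iids = {meta[i, 1]: i for i in members}
        children = [
            i
            for i in members
            if meta[i, 5] == "2" and meta[i, 2] in iids and meta[i, 3] in iids
        ]
        if len(children) != 1:
            logger.warning(
                "family %s skipped: need exactly one affected child with both "
                "parents present, found %d",
                fid,
                len(children),
            )
            continue
        child = children[0]
        trio_rows.append((fid, iids[meta[child, 2]], iids[meta[child, 3]], child))

    codes = np.full((len(trio_rows), n_loci), MISSING, dtype=np.int8)
    n_missing = np.zeros(n_loci, dtype=int)
    n_mendel = np.zeros(n_loci, dtype=int)
    for j, (fid, fa, mo, ch) in enumerate(trio_rows):
        for locus in range(n_loci):
            g = geno[[fa, mo, ch], locus, :]
            if np.any(g == "0"):
                n_missing[locus] += 1
                continue
            a, b, c = (int(np.sum(g[i] == risk[locus])) for i in range(3))
            a, b = max(a, b), min(a, b)
            idx = TRIO_INDEX.get((a, b, c))
            if idx is None:
                n_mendel[locus] += 1
                logger.warning(
                    "Mendelian inconsistency in family %s at %s", fid, loci["id"][locus]
                )
                continue
            codes[j, locus] = idx

    excluded = pd.DataFrame(
        {"id": loci["id"], "missing": n_missing, "mendel_error": n_mendel}
    )
    loci = loci.assign(risk_allele=risk)
    return TrioDataset(
        codes=codes,
        families=[fid for fid, *_ in trio_rows],
        loci=loci,
        excluded=excluded,
        provenance={
            "ped": str(ped_path),
            "map": str(map_path),
            "risk_allele_policy": risk_allele,
        },
    )


def write_ped(
    codes: np.ndarray,
    loci: pd.DataFrame,
    prefix,
    z: np.ndarray | None = None,
    alleles: tuple[str, str] = ("M", "N"),
) -> tuple[Path, Path]:
    """Write coded trios as text PED/MAP (+ optional truth-label TSV).

    ``codes`` is (n_trios, n_loci) canonical trio-type indices; parent
    genotype pairs are emitted unphased as counts of the risk allele
    ``alleles[0]``.  Returns the PED and MAP paths.
    """
    prefix = Path(prefix)
    risk, other = alleles
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    def genostr(copies: int) -> str:
        return " ".join([risk] * copies + [other] * (2 - copies))

    with open(ped_path, "w") as fh:
        for j in range(codes.shape[0]):
            fid = f"F{j + 1}"
            people = [
                (f"{fid}_1", "0", "0", "1", "1"),   # father
                (f"{fid}_2", "0", "0", "2", "1"),   # mother
                (f"{fid}_3", f"{fid}_1", f"{fid}_2", "1", "2"),  # child
            ]
            for person_idx, (iid, pat, mat, sex, pheno) in enumerate(people):
                fields = [fid, iid, pat, mat, sex, pheno]
                for locus in range(codes.shape[1]):
                    label = TRIO_LABELS[codes[j, locus]]
                    fields.append(genostr(int(label[person_idx])))
                fh.write(" ".join(fields) + "\n")
    with open(map_path, "w") as fh:
        for _, row in loci.iterrows():
            fh.write(f"{row['chrom']} {row['id']} {row.get('cm', 0)} {row['bp']}\n")
    if z is not None:
        truth_path = prefix.with_suffix(".truth.tsv")
        pd.DataFrame(
            {"fid": [f"F{j + 1}" for j in range(codes.shape[0])], "linked": z.astype(int)}
        ).to_csv(truth_path, sep="\t", index=False)
    return ped_path, map_path


def write_results(
    fits: dict[str, FitResult],
    table: pd.DataFrame,
    out_prefix,
    run_info: dict | None = None,
) -> dict[str, Path]:
    """Write the per-locus result table, posterior tables and JSON sidecar.

    ``table`` must contain :data:`RESULT_COLUMNS`; ``fits`` maps locus id
    to its fit for the posterior report.  Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table lacks columns: {missing}")
    paths: dict[str, Path] = {}

    results_path = out_prefix.with_suffix(".results.tsv")
    table.loc[:, RESULT_COLUMNS].to_csv(
        results_path, sep="\t", index=False, float_format="%.6g"
    )
    paths["results"] = results_path

    post_rows = []
    for locus_id, fit in fits.items():
        linked_i = set(linked_decision(fit, require_het_parent=False))
        linked_ii = set(linked_decision(fit, require_het_parent=True))
        for label, tau in zip(TRIO_LABELS, fit.tau1):
            post_rows.append(
                {
                    "locus": locus_id,
                    "trio_type": label,
                    "tau1": tau,
                    "linked_rule_i": int(label in linked_i),
                    "linked_rule_ii": int(label in linked_ii),
                }
            )
    post_path = out_prefix.with_suffix(".posteriors.tsv")
    pd.DataFrame(post_rows).to_csv(post_path, sep="\t", index=False, float_format="%.6g")
    paths["posteriors"] = post_path

    sidecar_path = out_prefix.with_suffix(".run.json")
    with open(sidecar_path, "w") as fh:
        json.dump(run_info or {}, fh, indent=2, sort_keys=True)
    paths["run"] = sidecar_path
    return paths
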