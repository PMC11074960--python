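"""Readers and writers for the pipeline's plain-text exchange formats.

All formats are tab-separated (CSV for STR tables, JSON for trees and
result reports) and round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .likelihood import DamageProfile
from .lineage import (
    CompositeProfile,
    HaplogroupNode,
    HaplogroupTree,
    MitoHaplotype,
    MitoVariant,
    STRProfile,
)
from .synthetic import FrequencyPanel, SiteObservation, TrueIBDSegment

__all__ = [
    "write_panel", "read_panel",
    "write_damage_profile", "read_damage_profile",
    "write_observations", "read_observations",
    "write_gl", "read_gl",
    "write_ibd_segments", "read_ibd_segments",
    "write_str_replicates", "read_str_replicates",
    "write_composite", "write_mito_pileup", "read_mito_pileup",
    "write_mito_haplotype", "read_mito_haplotype",
    "write_haplogroup_tree", "read_haplogroup_tree",
]

_SIDE_NAMES = {0: "5prime", 1: "3prime"}
_SIDE_CODES = {v: k for k, v in _SIDE_NAMES.items()}


# -- panel ------------------------------------------------------------------


def write_panel(panel: FrequencyPanel, path) -> None:
    df = panel.df.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path) -> FrequencyPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    pops = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
    return FrequencyPanel(df, pops)


# -- observations -----------------------------------------------------------


def write_observations(
    observations: Dict[str, List[SiteObservation]], path
) -> None:
    """Tab-separated per-read table: sample, siteId, allele, endDistance, endSide."""
    rows = []
    for sample, obs_list in observations.items():
        for obs in obs_list:
            for a, d, s in zip(obs.alleles, obs.dists, obs.sides):
                rows.append((sample, obs.site_id, int(a), int(d),
                             _SIDE_NAMES[int(s)]))
    pd.DataFrame(
        rows, columns=["sample", "siteId", "allele", "endDistance", "endSide"]
    ).to_csv(path, sep="\t", index=False)


def read_observations(
    path, panel: Optional[FrequencyPanel] = None
) -> Dict[str, List[SiteObservation]]:
    """Inverse of :func:`write_observations`.

    When a panel is given, every sample's list is aligned to panel order
    with empty observations at uncovered sites; otherwise sites appear in
    file order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"siteId": str, "sample": str})
    out: Dict[str, List[SiteObservation]] = {}
    for sample, g in df.groupby("sample", sort=True):
        per_site: Dict[str, List] = {}
        for row in g.itertuples():
            per_site.setdefault(row.siteId, []).append(
                (row.allele, row.endDistance, _SIDE_CODES[row.endSide])
            )
        site_order = (
            panel.df["id"].tolist() if panel is not None
            else list(dict.fromkeys(g["siteId"]))
        )
        obs_list = []
        for sid in site_order:
            reads = per_site.get(sid, [])
            obs_list.append(SiteObservation(
                sid,
                np.array([r[0] for r in reads], dtype=np.int8),
                np.array([r[1] for r in reads], dtype=np.int16),
                np.array([r[2] for r in reads], dtype=np.int8),
            ))
        out[str(sample)] = obs_list
    return out


# -- damage profile ---------------------------------------------------------


def write_damage_profile(profile: DamageProfile, path) -> None:
    """Tab-separated (end, distance, rate, fittedRate) plus fit header."""
    lines = [
        f"# amplitude5={profile.amplitude5:.8g}\tscale5={profile.scale5:.8g}",
        f"# amplitude3={profile.amplitude3:.8g}\tscale3={profile.scale3:.8g}",
        f"# warning={int(profile.warning)}",
        "end\tdistance\trate\tfittedRate",
    ]
    for side, rates in (("5prime", profile.rate5), ("3prime", profile.rate3)):
        code = 0 if side == "5prime" else 1
        fitted = profile.rate(code, np.arange(len(rates)))
        for d, (r, f) in enumerate(zip(rates, fitted)):
            lines.append(f"{side}\t{d}\t{r:.8g}\t{f:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_damage_profile(path) -> DamageProfile:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for part in line[1:].split("\t"):
                k, v = part.strip().split("=")
                meta[k] = float(v)
        elif line and not line.startswith("end\t"):
            end, dist, rate, _ = line.split("\t")
            rows.append((end, int(dist), float(rate)))
    n = max(d for _, d, _ in rows) + 1
    rate5, rate3 = np.zeros(n), np.zeros(n)
    for end, d, r in rows:
        (rate5 if end == "5prime" else rate3)[d] = r
    return DamageProfile(
        rate5=rate5,
        rate3=rate3,
        amplitude5=meta["amplitude5"],
        scale5=meta["scale5"],
        amplitude3=meta["amplitude3"],
        scale3=meta["scale3"],
        max_distance=n - 1,
        warning=bool(meta.get("warning", 0)),
    )


# -- genotype likelihoods ---------------------------------------------------


def write_gl(gl: pd.DataFrame, path, sample: str = "sample") -> None:
    df = gl.reset_index()
    df.insert(0, "sample", sample)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gl(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    return df.drop(columns=["sample"]).set_index("site_id")


# -- IBD segments -----------------------------------------------------------


def write_ibd_segments(segments: Iterable[TrueIBDSegment], path) -> None:
    """BED-like text with *genetic* (cM), not physical, coordinates."""
    rows = [(s.chrom, s.start_cm, s.end_cm, f"IBD{s.state}") for s in segments]
    pd.DataFrame(rows, columns=["chrom", "startCM", "endCM", "state"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_ibd_segments(path) -> List[TrueIBDSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        TrueIBDSegment(r.chrom, r.startCM, r.endCM, int(r.state[-1]))
        for r in df.itertuples()
    ]


# -- Y-STR ------------------------------------------------------------------


def write_str_replicates(replicates: Iterable[STRProfile], path) -> None:
    """CSV: sample, replicate, locus, allele, rfu."""
    rows = []
    for i, rep in enumerate(replicates):
        for locus, alleles in rep.loci.items():
            for allele, rfu in alleles:
                rows.append((rep.sample, i, locus, allele,
                             "" if rfu is None else rfu))
    pd.DataFrame(
        rows, columns=["sample", "replicate", "locus", "allele", "rfu"]
    ).to_csv(path, index=False)


def read_str_replicates(path) -> List[STRProfile]:
    df = pd.read_csv(path, dtype={"allele": str, "sample": str, "locus": str})
    out = []
    for (_, _), g in df.groupby(["sample", "replicate"], sort=True):
        loci: Dict[str, List] = {}
        for row in g.itertuples():
            rfu = None if pd.isna(row.rfu) else float(row.rfu)
            loci.setdefault(row.locus, []).append((row.allele, rfu))
        out.append(STRProfile(g["sample"].iloc[0], loci))
    return out


def write_composite(profile: CompositeProfile, path) -> None:
    """CSV rendering with the "(BT)" suffix for below-threshold alleles."""
    rows = []
    for locus in sorted(profile.loci):
        for a in profile.loci[locus]:
            rows.append((profile.sample, locus, a.render(), a.status))
    pd.DataFrame(
        rows, columns=["sample", "locus", "allele", "status"]
    ).to_csv(path, index=False)


# -- mitochondrial ----------------------------------------------------------


def write_mito_pileup(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_mito_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"position": str})


def write_mito_haplotype(hap: MitoHaplotype, path) -> None:
    """EMPOP-style variant list, one rCRS-relative call per line."""
    lines = [f"# sample: {hap.sample}",
             f"# covered: {hap.covered_range[0]}-{hap.covered_range[1]}"]
    for v in hap.variants:
        flag = " (mixed)" if v.heteroplasmic else ""
        lines.append(f"{v.render()}\t{v.type}{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mito_haplotype(path) -> MitoHaplotype:
    sample = "sample"
    covered = (0, 0)
    variants: List[MitoVariant] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# sample:"):
            sample = line.split(":", 1)[1].strip()
        elif line.startswith("# covered:"):
            lo, hi = line.split(":", 1)[1].strip().split("-")
            covered = (int(lo), int(hi))
        elif line.strip():
            call_str, type_str = line.split("\t")
            mixed = type_str.endswith(" (mixed)")
            vtype = type_str.replace(" (mixed)", "")
            # position is the longest numeric(.numeric) prefix
            i = 0
            while i < len(call_str) and (call_str[i].isdigit() or call_str[i] == "."):
                i += 1
            variants.append(
                MitoVariant(call_str[:i], call_str[i:], vtype, mixed)
            )
    return MitoHaplotype(sample, variants, covered)


# -- haplogroup tree --------------------------------------------------------


def write_haplogroup_tree(tree: HaplogroupTree, path) -> None:
    payload = [
        {
            "name": n.name,
            "parent": n.parent,
            "snps": [list(s) for s in n.defining_snps],
        }
        for n in tree.nodes.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_haplogroup_tree(path) -> HaplogroupTree:
    payload = json.loads(Path(path).read_text())
    return HaplogroupTree(
        HaplogroupNode(d["name"], d["parent"],
                       [tuple(s) for s in d["snps"]])
        for d in payload
    )
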