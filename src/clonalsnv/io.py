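"""Readers and writers for the pipeline's standard interchange formats.

Genotype tables are TSV (samples x markers, codes 0/1/2/NA); call sets move
as VCF; coded sequences as FASTA; trees as Newick; networks as an edge-list
TSV plus a NEXUS Network block readable by haplotype-network viewers.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filtering import CallSet, SiteFilterResult, SiteObservation
from .genotypes import GenotypeMatrix, MJNetwork
from .njtree import CodedSequence
from .popgen import AMOVAResult, PCoAResult

_GT_TO_VCF = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
_VCF_TO_GT = {v: k for k, v in _GT_TO_VCF.items()}
_VCF_TO_GT["0|0"] = "hom_ref"
_VCF_TO_GT["0|1"] = "het"
_VCF_TO_GT["1|0"] = "het"
_VCF_TO_GT["1|1"] = "hom_alt"


# -- genotype tables ---------------------------------------------------------

def read_genotype_table(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    try:
        return GenotypeMatrix(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_genotype_table(m: GenotypeMatrix, path: str) -> None:
    out = m.data.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


# -- VCF ---------------------------------------------------------------------

def write_vcf(callset: CallSet, path: str, clones: Optional[Sequence[str]] = None) -> None:
    """Write a minimal multi-sample VCF 4.2 with GT fields."""
    if clones is None:
        clones = sorted(callset.clones)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=clonalsnv:{callset.caller}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({k[0] for k in callset.calls})
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(clones) + "\n")
        for chrom, pos, ref, alt in callset.sorted_keys():
            genos = callset.calls[(chrom, pos, ref, alt)]
            gts = "\t".join(_GT_TO_VCF[genos[c]] for c in clones)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str, caller: Optional[str] = None) -> CallSet:
    """Read a multi-sample VCF of biallelic SNVs into a CallSet.

    Multiallelic records and non-SNV alleles are rejected with an explicit
    error naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    calls: Dict[Tuple[str, int, str, str], Dict[str, str]] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} "
                f"({var.REF}>{','.join(var.ALT)}); split or drop it first"
            )
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(
                f"{path}: non-SNV record at {var.CHROM}:{var.POS} ({ref}>{alt})"
            )
        genos = {}
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        for sample, gt_type in zip(samples, var.gt_types):
            genos[sample] = {0: "hom_ref", 1: "het", 3: "hom_alt"}.get(int(gt_type), "hom_ref")
        calls[(var.CHROM, var.POS, ref, alt)] = genos
    return CallSet(caller=caller or os.path.basename(path), calls=calls)


# -- FASTA -------------------------------------------------------------------

def write_fasta(seqs: Iterable[CodedSequence], path: str) -> None:
    records = [SeqRecord(Seq(s.chars), id=s.name, description="") for s in seqs]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> List[CodedSequence]:
    return [CodedSequence(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


# -- trees -------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


# -- networks ----------------------------------------------------------------

def write_network_edges(net: MJNetwork, path: str) -> None:
    rows = []
    for u, v, steps in net.edges:
        rows.append(
            {
                "node_a": u,
                "node_b": v,
                "steps": steps,
                "a_is_median": net.graph.nodes[u]["is_median"],
                "b_is_median": net.graph.nodes[v]["is_median"],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network_edges(path: str) -> List[Tuple[str, str, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(r.node_a, r.node_b, int(r.steps)) for r in df.itertuples()]


def write_network_nexus(net: MJNetwork, path: str) -> None:
    """NEXUS file with a Network block (vertices + edges)."""
    nodes = sorted(net.graph.nodes)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Network;\n")
        fh.write(f"DIMENSIONS nvertices={len(nodes)} "
                 f"nedges={net.graph.number_of_edges()};\n")
        fh.write("VERTICES\n")
        for i, name in enumerate(nodes, 1):
            kind = "median" if net.graph.nodes[name]["is_median"] else "observed"
            fh.write(f"  {i} {name} [{kind}],\n")
        fh.write(";\nEDGES\n")
        index = {name: i for i, name in enumerate(nodes, 1)}
        for k, (u, v, steps) in enumerate(net.edges, 1):
            fh.write(f"  {k} {index[u]} {index[v]} [steps={steps}],\n")
        fh.write(";\nEND;\n")


# -- analysis tables ---------------------------------------------------------

def write_audit_table(results: Sequence[SiteFilterResult], path: str,
                      observations: Optional[Dict[Tuple, Dict[str, SiteObservation]]] = None
                      ) -> None:
    rows = []
    for res in results:
        for clone, reasons in sorted(res.reasons.items()):
            row = {
                "chrom": res.key[0], "pos": res.key[1],
                "ref": res.key[2], "alt": res.key[3],
                "clone": clone,
                "site_pass": res.passed,
                "reasons": ";".join(reasons) or ".",
            }
            if observations is not None:
                obs = observations.get(res.key, {}).get(clone)
                if obs is not None:
                    row["dp"] = obs.dp
                    row["vaf"] = round(obs.vaf, 4) if obs.dp else float("nan")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_amova_table(result: AMOVAResult, path: str) -> None:
    df = pd.DataFrame(
        [
            {"source": "among_groups", "df": result.df_among, "SS": result.ss_among,
             "MS": result.ss_among / result.df_among, "variance": result.va},
            {"source": "within_groups", "df": result.df_within, "SS": result.ss_within,
             "MS": result.vw, "variance": result.vw},
            {"source": "total", "df": result.df_among + result.df_within,
             "SS": result.ss_total, "MS": float("nan"),
             "variance": result.va + result.vw},
        ]
    )
    with open(path, "w") as fh:
        fh.write(f"# Phi_PT={result.phi_pt:.4f} (raw {result.phi_pt_raw:.4f}) "
                 f"p={result.p_value} n_perm={result.n_permutations} n0={result.n0:.4f}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_pcoa_table(result: PCoAResult, path: str) -> None:
    with open(path, "w") as fh:
        pct = " ".join(f"{p:.1f}" for p in result.percent_variance)
        fh.write(f"# percent_variance: {pct}\n")
        result.as_frame().to_csv(fh, sep="\t")
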