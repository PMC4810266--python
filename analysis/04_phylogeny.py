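#!/usr/bin/env python
"""Phyletic clustering and core-gene phylogeny of the simulated family.

Builds (i) the presence/absence dendrogram over gene clusters (Pearson
distance, UPGMA) and (ii) per-marker NJ trees from progressive alignments
of the five core genes, their concatenated-alignment tree, and the SPR
supertree.  All trees are written as newick under results/trees/.
"""

from pathlib import Path

from Bio import SeqIO

from gvlineage import genome_io, phyletics
from gvlineage.orthology import qualify
from gvlineage.pangenome import greedy_cluster
from gvlineage.pipeline import analyze_family

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genomes = [
        genome_io.read_genbank(p)
        for p in sorted((ROOT / "family" / "genomes").glob("*.gb"))
    ]
    out = ROOT / "trees"
    out.mkdir(parents=True, exist_ok=True)

    proteins = {
        qualify(g.genome_id, pid): seq
        for g in genomes
        for pid, seq in g.proteins().items()
    }
    clusters = greedy_cluster(proteins)
    matrix = phyletics.build_matrix(clusters, [g.genome_id for g in genomes])
    dend = phyletics.upgma(phyletics.pearson_distance(matrix))
    (out / "phyletic_dendrogram.nwk").write_text(dend.newick() + "\n")
    print("phyletic dendrogram:", dend.newick())

    seeds = {
        r.id: str(r.seq)
        for r in SeqIO.parse(ROOT / "family" / "truth" / "markers.faa", "fasta")
    }
    res = analyze_family(genomes, marker_seeds=seeds)
    for gene, tree in res.gene_trees.items():
        (out / f"{gene}.nwk").write_text(tree.to_newick() + "\n")
        print(f"{gene:<22} {tree.to_newick(lengths=False)}")
    (out / "concat.nwk").write_text(res.concat_tree.to_newick() + "\n")
    print("concatenated tree:    ", res.concat_tree.to_newick(lengths=False))
    (out / "supertree.nwk").write_text(res.supertree.newick + "\n")
    print(
        f"supertree ({res.supertree.method}, total SPR distance "
        f"{res.supertree.total_distance}): {res.supertree.newick}"
    )


if __name__ == "__main__":
    main()
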