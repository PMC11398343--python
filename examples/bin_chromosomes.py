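"""Pack whole chromosomes into similar-sized bins with LPT.

Uses rounded human-genome chromosome lengths and the production default of
~200 Mbp per bin.  Each printed bin is the workload of one aligner
instance; the spread between the heaviest and lightest bin shows how close
the longest-processing-time-first heuristic gets to a perfect split
without ever cutting a chromosome (which would create straddling
alignments at the cut and force coordinate lifting afterwards).
"""

from diagpart import Chromosome, bins_for_target_size, pair_bins

# approximate hg38 chromosome lengths, Mbp
hg38 = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156, "chrY": 57,
}
chroms = [Chromosome(n, l * 1_000_000) for n, l in hg38.items()]

bins = bins_for_target_size(chroms, target_bin_size=200_000_000)
total = sum(c.length for c in chroms)
print(f"{len(chroms)} chromosomes, {total/1e9:.2f} Gbp total -> {len(bins)} bins")
for b in bins:
    names = ",".join(c.name for c in b.members)
    print(f"  bin {b.id}: {b.load/1e6:7.0f} Mbp  [{names}]")
loads = [b.load for b in bins]
print(f"load spread: max/min = {max(loads)/min(loads):.3f}")

pairs = pair_bins(bins[:2], bins[:3])
print(f"\naligning 2 target bins x 3 query bins -> {len(pairs)} instance pairs")
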