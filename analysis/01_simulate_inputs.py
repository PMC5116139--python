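#!/usr/bin/env python
"""Generate the synthetic study inputs: a 2 Mb genome with five TE families
(three L1 families of increasing age, an enhancer-like LTR family, a SINE),
plus the ChIP experiment binding the young L1s and the LTR enhancers.

Writes the RepeatMasker-style annotation, peak BEDs, multi-hit SAM and truth
tables under results/sim/ (the genome FASTA, being large, goes to scratch/).
"""

from pathlib import Path

from retroepi import genome_annotation as ga
from retroepi import read_assignment as ra
from retroepi import synthetic_data as sd
from retroepi import te_enrichment as te

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 1
BINDING = {"L1Md_T": 0.8, "RLTR13D6": 0.5}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    cfg = sd.SimulationConfig(seed=SEED)
    cfg.to_json(OUT / "config.json")
    sim = sd.simulate_genome(cfg)
    ga.write_fasta(sim.genome, SCRATCH / "genome.fa")
    ga.write_fasta(sim.consensus, OUT / "consensus.fa")
    ga.write_repeatmasker(sim.copies, OUT / "repeats.out")
    sim.truth.to_csv(OUT / "te_truth.tsv", sep="\t", index=False)
    print(f"genome: {sum(sim.chrom_sizes.values()):,} bp, {len(sim.copies)} TE copies")
    print(sim.truth.groupby("family").size().to_string())

    chip = sd.simulate_chip(sim, BINDING, seed=SEED + 1)
    ga.write_bed([p.interval for p in chip.peaks_inclusive], OUT / "peaks_inclusive.bed")
    ga.write_bed([p.interval for p in chip.peaks_unique], OUT / "peaks_unique.bed")
    ra.write_sam_records(chip.records, sim.chrom_sizes, SCRATCH / "chip_reads.sam")
    chip.truth.to_csv(OUT / "peak_truth.tsv", sep="\t", index=False)
    n_multi = sum(1 for r in chip.records if len(r.hits) > 1)
    print(
        f"chip: {len(chip.peaks_inclusive)} inclusive / {len(chip.peaks_unique)} "
        f"unique peaks, {len(chip.records)} reads ({n_multi} multi-hit)"
    )


if __name__ == "__main__":
    main()
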