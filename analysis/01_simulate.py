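"""Generate the synthetic eye-maturation study.

Emits the full input bundle — multi-database transcript annotation, 25-mer
probe alignments, 3/4/5 dpf intensity matrices, GO/KEGG catalogs, homolog
hits, disease loci, and larval VMR traces — plus the ground-truth tables
used by the later steps to score recovery.  Raw inputs land under scratch/study;
derived tables under results/.
"""

from pathlib import Path

from retinomature.config import SimConfig
from retinomature.synthgen import simulate_all

OUT = Path(__file__).resolve().parent.parent / "scratch" / "study"
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED, n_genes=150, n_larvae=6,
                    settle_minutes=10, phase_minutes=5)
    paths = simulate_all(cfg, OUT)
    print(f"wrote {len(paths)} files under {OUT}")
    print(f"  genes simulated: {cfg.n_genes}; stages: "
          f"{', '.join(s for s, _ in cfg.groups)}; "
          f"{cfg.n_probes_per_probeset} probes per probe set")
    print(f"  spiked DE fraction {cfg.frac_de} at |log2FC|={cfg.log2fc_de}; "
          f"splice discordance +/-{cfg.splice_delta}")


if __name__ == "__main__":
    main()
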