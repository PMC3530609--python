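"""Configuration objects for simulation and pipeline runs.

``SimConfig`` holds the experimental-design constants the synthetic data
generator emulates: a three-time-point (3/4/5 dpf) eye microarray design with
three biological replicates per stage, Affymetrix-style 11-probe probe sets,
and a visual motor response (VMR) protocol of 30 min settling followed by
four 20 min light ON/OFF cycles.  ``RunConfig`` wires input paths and stage
thresholds for an end-to-end pipeline run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its legal range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study, all derived from one master seed.

    Fractions are in [0, 1]; counts are >= 1; ``noise_sd`` > 0.  Two
    configs that compare equal produce byte-identical output files.
    """

    seed: int = 0
    # genome / annotation scale
    n_chromosomes: int = 25          # zebrafish karyotype
    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (1, 3)
    # probe design (Affymetrix convention: 25-mers, 11 probes per set)
    probe_length: int = 25
    n_probes_per_probeset: int = 11
    n_probesets: int = 2000
    frac_problem_probes: float = 0.10
    # expression design: (stage label, n replicates)
    groups: tuple[tuple[str, int], ...] = (("3dpf", 3), ("4dpf", 3), ("5dpf", 3))
    frac_de: float = 0.075
    log2fc_de: float = 1.5
    noise_sd: float = 0.35
    frac_multi_probeset_genes: float = 0.30
    frac_splice: float = 0.10
    splice_delta: float = 1.25       # |SI| spiked into discordant genes
    frac_low_signal: float = 0.10
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    low_baseline_log2_range: tuple[float, float] = (2.0, 4.5)
    # functional annotation
    n_terms: int = 50
    term_size_range: tuple[int, int] = (5, 40)
    spiked_pathway_size: int = 30
    spiked_pathway_de_fraction: float = 0.5
    homolog_coverage: float = 0.8
    locus_count: int = 12
    # behaviour traces
    settle_minutes: float = 30.0
    phase_minutes: float = 20.0
    light_cycles: int = 4            # ON/OFF pairs after settling
    n_larvae: int = 12
    baseline_rate: float = 0.1
    burst_amplitude: float = 0.9
    burst_decay_s: float = 3.0
    burst_jitter_sd: float = 0.15
    treatment_effect: float = 0.4    # multiplier on burst amplitude, treated group
    trace_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_splice", "frac_low_signal",
                     "frac_problem_probes", "frac_multi_probeset_genes",
                     "spiked_pathway_de_fraction", "homolog_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        for name in ("n_chromosomes", "n_genes", "n_probes_per_probeset",
                     "n_probesets", "n_terms", "locus_count", "light_cycles",
                     "n_larvae", "probe_length"):
            v = getattr(self, name)
            if v < 1:
                raise ConfigurationError(f"{name}={v} must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError("transcripts_per_gene must be (lo, hi) with 1 <= lo <= hi")
        if self.spiked_pathway_size > self.n_genes:
            raise ConfigurationError("spiked_pathway_size cannot exceed n_genes")
        for stage, n in self.groups:
            if n < 2:
                raise ConfigurationError(
                    f"group {stage!r} has {n} replicates; >= 2 required (variance undefined)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kw = dict(d)
        if "transcripts_per_gene" in kw:
            kw["transcripts_per_gene"] = tuple(kw["transcripts_per_gene"])
        if "groups" in kw:
            kw["groups"] = tuple((str(s), int(n)) for s, n in kw["groups"])
        for k in ("baseline_log2_range", "low_baseline_log2_range", "term_size_range"):
            if k in kw:
                kw[k] = tuple(kw[k])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulate keys: {sorted(unknown)}")
        return cls(**kw)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` delegates input generation to the synthetic module,
    or every input path must point at an existing file.  Threshold defaults
    are the published analysis settings: signal floor log2 6, q < 0.05,
    fold change >= 1.5 or <= 0.67, splicing-index gate [-1, 1], homolog
    filter 30% identity over 30% length, >= 3 probes per probe set.
    """

    outdir: Path
    simulate: Optional[SimConfig] = None
    # explicit input paths (ignored when simulate is set)
    annotation_files: list[Path] = field(default_factory=list)
    probe_alignments: Optional[Path] = None
    intensities: Optional[Path] = None
    samples: Optional[Path] = None
    zebrafish_gmt: Optional[Path] = None
    human_gmt: Optional[Path] = None
    homolog_hits: Optional[Path] = None
    human_gene_bed: Optional[Path] = None
    loci: Optional[Path] = None
    traces: Optional[Path] = None
    term_categories: Optional[Path] = None
    # stage thresholds
    contrast: str = "5v3"
    signal_floor: float = 6.0
    q_cut: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.67
    si_gate: float = 1.0
    homolog_min_identity: float = 30.0
    homolog_min_length_frac: float = 0.30
    min_probes: int = 3
    ignore_strand: bool = False
    peak_window_s: int = 30
    base_window_s: int = 30
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.fc_up <= 1:
            raise ConfigurationError("fc_up must be > 1")
        if self.fc_down >= 1:
            raise ConfigurationError("fc_down must be < 1")
        if not 0 < self.q_cut < 1:
            raise ConfigurationError("q_cut must be in (0, 1)")
        if self.min_probes < 1:
            raise ConfigurationError("min_probes must be >= 1")
        if self.si_gate <= 0:
            raise ConfigurationError("si_gate must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        kw = {}
        path_keys = {"probe_alignments", "intensities", "samples", "zebrafish_gmt",
                     "human_gmt", "homolog_hits", "human_gene_bed", "loci",
                     "traces", "term_categories"}
        for k, v in raw.items():
            if k == "annotation_files":
                kw[k] = [Path(p) for p in v]
            elif k in path_keys and v is not None:
                kw[k] = Path(v)
            else:
                kw[k] = v
        cfg = cls(**kw)
        if sim is not None:
            cfg.simulate = SimConfig.from_dict(sim)
        return cfg
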