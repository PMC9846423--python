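"""Ground-truth-labeled synthetic chromatograms and sample sets.

The generator emulates the signal model the peak-ratio formulas invert: at
each called base the four dye channels carry Gaussian-noised peak heights,
and at a CpG the C/T (forward) or G/A (reverse) heights are proportional
to the methylated/unmethylated molecule fractions.  Conversion-control
cytosines split their signal between the converted and unconverted base
according to the simulated bisulfite conversion efficiency.  Read
extremities are degraded (mixed peaks, low Phred) to exercise the trimming
stage.  Everything is deterministic per seed.

The simulator's core assumption — peak height linear in molecule fraction —
is exactly the measurement model of the quantification formulas; recovery
tests therefore validate the pipeline plumbing, not the photochemistry of
real dye signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import trace_io
from .reference import ReferenceRegion, bisulfite_convert, find_cpg_sites
from .trace_io import ChromatogramTrace

_COL = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


@dataclass
class SimParams:
    """Study conditions for one simulated read."""

    ref: ReferenceRegion
    true_methylation: tuple[float, ...]   # percent, one per CpG site
    conversion_efficiency: float = 0.99
    direction: str = "forward"
    peak_scale: float = 1000.0
    noise_sd: float = 0.02                # fraction of peak_scale
    bad_end_length: int = 15
    phred_good: int = 50
    phred_bad: int = 8
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.true_methylation, dtype=float)
        if ((m < 0) | (m > 100)).any():
            raise ValueError("true methylation percentages must lie in [0, 100]")
        if not (0 <= self.conversion_efficiency <= 1):
            raise ValueError("conversion efficiency must lie in [0, 1]")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")


def make_reference(name: str = "synthRegion", length: int = 400,
                   n_cpg: int = 8, seq_start: int = 6000,
                   amplified_strand: str = "plus", end_margin: int = 40,
                   seed: int = 0) -> ReferenceRegion:
    """Random reference region with a controlled number of CpG sites.

    The backbone sequence is drawn without any CG dinucleotide, then *n_cpg*
    CG dinucleotides are planted at evenly spread positions at least
    *end_margin* bases from either extremity (so degraded read ends never
    overlap a CpG at the default settings).
    """
    rng = np.random.default_rng(seed)
    seq = []
    for _ in range(length):
        choices = "ACGT" if (not seq or seq[-1] != "C") else "ACT"
        seq.append(choices[rng.integers(len(choices))])
    if n_cpg > 0:
        span = length - 2 * end_margin - 2
        if span < 3 * n_cpg:
            raise ValueError("region too short for the requested CpG count")
        positions = end_margin + np.round(
            np.linspace(0, span, n_cpg)).astype(int)
        for p in positions:
            seq[p] = "C"
            seq[p + 1] = "G"
            # planting CG after a C would create an unplanned extra site
            if p >= 1 and seq[p - 1] == "C":
                seq[p - 1] = "A"
            if p + 2 < length and seq[p + 2] == "G" and seq[p + 1] == "C":
                seq[p + 2] = "A"
    sequence = "".join(seq)
    return ReferenceRegion(
        name=name, sequence=sequence, seq_start=seq_start,
        seq_end=seq_start + length - 1, amplified_strand=amplified_strand,
    )


def simulate_trace(params: SimParams) -> tuple[ChromatogramTrace, dict]:
    """Simulate one chromatogram read of the full converted template.

    Returns the trace and a truth record with the per-CpG methylation,
    conversion efficiency and the clean (non-degraded) window.
    """
    ref = params.ref
    templates = bisulfite_convert(ref)
    sites = find_cpg_sites(ref)
    m = np.asarray(params.true_methylation, dtype=float)
    if len(m) != len(sites):
        raise ValueError(
            f"{len(m)} methylation values for {len(sites)} CpG sites")
    rng = np.random.default_rng(params.seed)

    forward = params.direction == "forward"
    template = templates.sense if forward else templates.antisense
    L = len(template)
    scale = params.peak_scale

    heights = np.zeros((L, 4))
    # backbone: one dominant peak per template base (N -> flat mixture)
    for i, b in enumerate(template):
        if b in _COL:
            heights[i, _COL[b]] = scale
        else:
            heights[i, :] = scale / 4.0

    # CpG columns: methylation-dependent two-channel mixture
    for site, mi in zip(sites, m):
        p_sense = ref.cpg_sense_position(site)
        if forward:
            pos = p_sense - 1
            hi, lo = _COL["C"], _COL["T"]
        else:
            pos = templates.mirror(p_sense) - 1
            hi, lo = _COL["G"], _COL["A"]
        heights[pos, :] = 0.0
        heights[pos, hi] = scale * mi / 100.0
        heights[pos, lo] = scale * (1.0 - mi / 100.0)

    # conversion-control columns: efficiency-dependent mixture
    eff = params.conversion_efficiency
    for p_sense in templates.non_cpg_c_positions_sense:
        if forward:
            pos = p_sense - 1
            conv, unconv = _COL["T"], _COL["C"]
        else:
            pos = templates.mirror(p_sense) - 1
            conv, unconv = _COL["A"], _COL["G"]
        heights[pos, :] = 0.0
        heights[pos, conv] = scale * eff
        heights[pos, unconv] = scale * (1.0 - eff)

    heights += rng.normal(0.0, params.noise_sd * scale, size=(L, 4))

    phred = np.full(L, params.phred_good, dtype=int)
    bad = min(params.bad_end_length, L // 2)
    if bad > 0:
        for sl in (slice(0, bad), slice(L - bad, L)):
            n = heights[sl].shape[0]
            # mixed, saturating-ish signal on all four channels
            heights[sl] = rng.uniform(0.15 * scale, 0.4 * scale, size=(n, 4))
            phred[sl] = params.phred_bad

    heights = np.clip(np.round(heights), 0, 32767).astype(int)
    called = "".join(BASES[i] for i in heights.argmax(axis=1))

    trace = ChromatogramTrace(
        read_id=f"sim_{ref.name}_{params.direction}_{params.seed}",
        called_bases=called,
        phred=phred,
        peak_heights=heights,
    )
    truth = {
        "true_methylation": {s.c_coordinate: float(mi)
                             for s, mi in zip(sites, m)},
        "conversion_efficiency": eff,
        "direction": params.direction,
        "clean_window": (bad + 1, L - bad),
    }
    return trace, truth


def simulate_sample(base: SimParams, outdir, stem: str,
                    seed: int) -> tuple[list[Path], dict]:
    """Write one sample's forward+reverse reads as unlabeled .ab1 files.

    The two files are numbered #1/#2 in a random order so the pipeline's
    direction auto-detection is actually exercised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    traces = []
    for i, direction in enumerate(("forward", "reverse")):
        p = replace(base, direction=direction, seed=int(seed) * 2 + i)
        trace, truth = simulate_trace(p)
        traces.append((trace, truth))
    if rng.random() < 0.5:
        traces.reverse()
    paths = []
    for i, (trace, _) in enumerate(traces, start=1):
        path = outdir / f"{stem}_{i}.ab1"
        trace_io.write_abif(trace, path)
        paths.append(path)
    return paths, traces[0][1] | {"directions": [t[1]["direction"] for t in traces]}


def simulate_experiment(outdir, ref: ReferenceRegion,
                        group_methylation: dict[str, tuple[float, ...]],
                        n_replicates: int = 3,
                        collection: str = "colA",
                        experiment_type: str = "direct",
                        base: SimParams | None = None,
                        seed: int = 0) -> dict:
    """Simulate a full grouped experiment layout on disk.

    For each group in *group_methylation* and each replicate, a forward and
    a reverse read are written as ``.ab1`` files.  For ``direct``
    experiments the group's methylation vector is used as-is for every
    replicate; for ``cloning`` experiments each clone's per-CpG status is
    drawn Bernoulli(p/100) and the clone is simulated fully methylated or
    fully unmethylated per site.

    Writes the reference FASTA, a batch manifest CSV (one row per sample,
    consumable by the batch command) and a truth CSV; returns their paths
    and the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = find_cpg_sites(ref)
    if base is None:
        base = SimParams(ref=ref,
                         true_methylation=tuple([0.0] * len(sites)))
    rng = np.random.default_rng(seed)

    fasta = outdir / f"{ref.name}.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i:i + 70] + "\n")

    manifest_rows = []
    truth_rows = []
    for group, meth in group_methylation.items():
        meth = np.asarray(meth, dtype=float)
        if len(meth) != len(sites):
            raise ValueError(f"group {group!r}: {len(meth)} methylation values "
                             f"for {len(sites)} CpG sites")
        for rep in range(1, n_replicates + 1):
            if experiment_type == "cloning":
                sample_meth = 100.0 * (rng.random(len(sites)) < meth / 100.0)
            else:
                sample_meth = meth
            stem = f"{collection}_{group}_{rep}"
            sample_seed = int(rng.integers(0, 2**30))
            paths, truth = simulate_sample(
                replace(base, true_methylation=tuple(sample_meth)),
                outdir / "traces", stem, sample_seed)
            manifest_rows.append({
                "sequence_name": ref.name,
                "collection": collection,
                "group": group,
                "replicate_or_clone": str(rep),
                "experiment_type": experiment_type,
                "fasta": str(fasta),
                "seq_start": ref.seq_start,
                "seq_end": ref.seq_end,
                "strand": ref.amplified_strand,
                "ab1_1": str(paths[0]),
                "ab1_2": str(paths[1]),
            })
            for site, mi in zip(sites, sample_meth):
                truth_rows.append({
                    "group": group,
                    "replicate_or_clone": str(rep),
                    "cpg_index": site.index,
                    "c_coordinate": site.c_coordinate,
                    "true_methylation": float(mi),
                    "conversion_efficiency": base.conversion_efficiency,
                })

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest_path = outdir / "manifest.csv"
    truth_path = outdir / "truth.csv"
    manifest.to_csv(manifest_path, index=False)
    truth.to_csv(truth_path, index=False)
    return {
        "fasta": fasta,
        "manifest": manifest_path,
        "truth": truth_path,
        "manifest_table": manifest,
        "truth_table": truth,
        "trace_dir": outdir / "traces",
    }
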