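"""Paired synthetic single-cell / bulk / phenotype data with planted truth.

The generator emulates the assumptions the selection method rests on:
cells fall into G groups, each over-expressing a disjoint block of
marker genes (its "program"); bulk samples are convex mixtures of the
group programs; and the phenotype is driven by the abundance of one
planted group. Case samples up-weight the planted positive group's
program by a factor ``effect`` (binary mode); in survival mode the
hazard is log-linear in the sample's planted-program weight.

Single-cell counts are negative binomial (dispersion 0.5 by default);
bulk counts are Poisson around the noisy mixture. All randomness flows
from one seed, so regeneration is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GeneMatrix, PhenotypeVector
from .errors import ValidationError


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    n_groups: int
    planted_positive: int
    planted_negative: int  # -1 when absent
    programs: np.ndarray  # genes x groups expected expression
    marker_blocks: list  # list of index arrays, one per group
    effect: float
    dispersion: float
    seed: int
    cell_groups: np.ndarray  # true group per cell
    expected_labels: np.ndarray  # "positive" / "negative" / "background"
    sample_weights: np.ndarray  # samples x groups mixture weights


def _nb_counts(rng, mean, dispersion):
    """Negative binomial with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate(n_genes=500, n_cells=500, n_samples=60, n_groups=5, effect=3.0,
             mode="binary", seed=0, dispersion=0.5, marker_size=40,
             baseline_mean=2.0, marker_boost=6.0, bulk_noise_sd=0.25,
             bulk_depth=100_000, dirichlet_conc=None, plant_negative=False):
    """Generate (sc GeneMatrix, bulk GeneMatrix, PhenotypeVector, truth).

    Parameters mirror the planted model: ``effect`` is the multiplicative
    up-weighting of the planted group's mixture weight in case samples
    (or the per-SD hazard ratio in survival mode); ``effect = 1`` is the
    null. Group programs occupy disjoint ``marker_size`` gene blocks.
    """
    if n_cells < 10 * n_groups:
        raise ValidationError("need at least 10 cells per group")
    if n_samples < 20:
        raise ValidationError("need at least 20 samples")
    if n_genes < 200:
        raise ValidationError("need at least 200 genes")
    if effect <= 0:
        raise ValidationError("effect must be positive")
    if n_groups * marker_size > n_genes:
        raise ValidationError("marker blocks exceed the gene count")
    if mode not in ("binary", "survival"):
        raise ValidationError("mode must be 'binary' or 'survival'")
    if dirichlet_conc is None:
        # binary: the phenotype is an explicit case/control composition
        # shift on a stable background; survival: the hazard tracks the
        # natural between-sample composition, which must therefore vary
        dirichlet_conc = 30.0 if mode == "binary" else 5.0
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    sample_ids = [f"sample_{i:03d}" for i in range(n_samples)]

    baseline = rng.gamma(2.0, baseline_mean / 2.0, size=n_genes) + 0.05
    programs = np.tile(baseline[:, None], (1, n_groups))
    marker_blocks = []
    for g in range(n_groups):
        block = np.arange(g * marker_size, (g + 1) * marker_size)
        marker_blocks.append(block)
        programs[block, g] *= marker_boost

    # cells: equal group sizes (remainder spread over the first groups)
    cell_groups = np.sort(np.arange(n_cells) % n_groups)
    sc_counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for g in range(n_groups):
        cols = np.flatnonzero(cell_groups == g)
        mean = np.tile(programs[:, g][:, None], (1, cols.size))
        sc_counts[:, cols] = _nb_counts(rng, mean, dispersion)

    planted_pos = 0
    planted_neg = 1 if plant_negative else -1

    # bulk: Dirichlet mixtures of group programs
    weights = rng.dirichlet(np.full(n_groups, dirichlet_conc), size=n_samples)
    if mode == "binary":
        y = np.zeros(n_samples)
        y[n_samples // 2 :] = 1.0
        weights = weights.copy()
        weights[y == 1, planted_pos] *= effect
        if planted_neg >= 0:
            weights[y == 1, planted_neg] /= effect
        weights /= weights.sum(axis=1, keepdims=True)
    bulk_mean = programs @ weights.T  # genes x samples
    noise = np.exp(rng.normal(0.0, bulk_noise_sd, size=bulk_mean.shape))
    bulk_mean = bulk_mean * noise
    bulk_mean = bulk_mean / bulk_mean.sum(axis=0, keepdims=True) * bulk_depth
    bulk_counts = rng.poisson(bulk_mean)

    if mode == "binary":
        pheno = PhenotypeVector(sample_ids, "binary", y=y)
    else:
        z = weights[:, planted_pos]
        z = (z - z.mean()) / z.std()
        hazard = np.exp(np.log(effect) * z)
        t_event = rng.exponential(1.0 / hazard)
        # uniform censoring window sized for roughly 30% censoring under
        # a unit exponential: solve (1 - e^-c)/c = 0.3 => c ~ 3.2, i.e.
        # about 4.6 median event times
        c = rng.uniform(0.0, 4.6 * np.median(t_event), size=n_samples)
        time = np.minimum(t_event, c)
        status = (t_event <= c).astype(float)
        time = np.maximum(time, 1e-6)
        pheno = PhenotypeVector(sample_ids, "survival", time=time,
                                status=status)

    expected = np.full(n_cells, "background", dtype=object)
    expected[cell_groups == planted_pos] = "positive"
    if planted_neg >= 0:
        expected[cell_groups == planted_neg] = "negative"

    sc = GeneMatrix(gene_ids, cell_ids, sc_counts.astype(float),
                    stage="raw_counts")
    bulk = GeneMatrix(gene_ids, sample_ids, bulk_counts.astype(float),
                      stage="raw_counts")
    truth = SyntheticTruth(
        n_groups=n_groups, planted_positive=planted_pos,
        planted_negative=planted_neg, programs=programs,
        marker_blocks=marker_blocks, effect=effect, dispersion=dispersion,
        seed=seed, cell_groups=cell_groups, expected_labels=expected,
        sample_weights=weights,
    )
    return sc, bulk, pheno, truth


def write_dataset(sc, bulk, pheno, truth, outdir):
    """Write the three input files (TSV) plus a truth JSON."""
    import json
    from pathlib import Path

    from .io import write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(sc, outdir / "sc_counts.tsv")
    write_expression(bulk, outdir / "bulk_counts.tsv")
    with open(outdir / "phenotype.tsv", "w") as fh:
        if pheno.mode == "binary":
            fh.write("sample_id\tlabel\n")
            for s, v in zip(pheno.sample_ids, pheno.y):
                fh.write(f"{s}\t{int(v)}\n")
        else:
            fh.write("sample_id\ttime\tstatus\n")
            for s, t, e in zip(pheno.sample_ids, pheno.time, pheno.status):
                fh.write(f"{s}\t{t:.10g}\t{int(e)}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            dict(
                n_groups=truth.n_groups,
                planted_positive=truth.planted_positive,
                planted_negative=truth.planted_negative,
                effect=truth.effect,
                dispersion=truth.dispersion,
                seed=truth.seed,
                cell_groups=truth.cell_groups.tolist(),
                expected_labels=list(truth.expected_labels),
            ),
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
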