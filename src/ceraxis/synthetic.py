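"""Synthetic cohort generator with a planted ceRNA axis.

Emulates a small two-group (responder/nonresponder) transcriptomic study in
which one or more lncRNA-miRNA-mRNA axes carry the sponge signature: within
each planted axis the lncRNA and mRNA are co-expressed through a shared
latent factor while the miRNA loads on the same factor with opposite sign,
and the groups differ by a standardized effect with the miRNA *up* and the
lncRNA/mRNA *down* in responders.  All remaining features are independent
noise, so every downstream stage (differential expression, coexpression
centrality, target prediction, axis screening, response prediction) has an
unambiguous ground truth.

Sequences are generated alongside the expression tables: each planted
miRNA-target pair receives a complementary binding site containing a
canonical 8mer seed match, with extended 3'-supplementary pairing on the
lncRNA so the lncRNA site is both higher-scoring and more thermodynamically
stable than the mRNA site.  Decoy targets are rejection-sampled to be free
of any >=6mer seed match to a planted miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NONRESPONDER, RESPONDER, SequenceSet

_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def revcomp_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic cohorts.

    ``axis_effect`` is the standardized mean group difference (Cohen's d,
    relative to the within-group standard deviation) applied to every member
    of a planted axis; ``axis_corr`` is the loading of the shared latent
    factor and controls the within-axis correlation strength; ``noise_sd``
    is the residual log2-scale standard deviation.
    """

    n_responders: int = 3
    n_nonresponders: int = 3
    n_lnc: int = 50
    n_mir: int = 20
    n_mrna: int = 100
    n_planted_axes: int = 1
    axis_effect: float = 2.0
    axis_corr: float = 0.9
    noise_sd: float = 0.02
    seq_len_mir: int = 22
    seq_len_target: int = 300
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_responders", "n_nonresponders", "n_lnc", "n_mir", "n_mrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_planted_axes < 0:
            raise ValueError("n_planted_axes must be >= 0")
        if self.n_planted_axes > min(self.n_lnc, self.n_mir, self.n_mrna):
            raise ValueError("more planted axes than features in some RNA class")
        if not 0.0 <= self.axis_corr <= 1.0:
            raise ValueError(f"axis_corr must lie in [0, 1], got {self.axis_corr}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.seq_len_mir < 8:
            raise ValueError("seq_len_mir must be >= 8")
        if self.seq_len_target < 40:
            raise ValueError("seq_len_target must be >= 40 to host a binding site")


@dataclass
class GroundTruth:
    """What was planted: axes, binding-site coordinates, group effects."""

    planted_axes: list[tuple[str, str, str]] = field(default_factory=list)
    #: target id -> list of (start, end), 0-based half-open coordinates of the
    #: 8mer seed-match region on the target sequence
    planted_site_positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: feature id -> signed log2 group difference (responder - nonresponder)
    true_group_effects: dict[str, float] = field(default_factory=dict)


def _feature_ids(config: SyntheticConfig) -> dict[str, list[str]]:
    return {
        "lncRNA": [f"LNC{i:04d}" for i in range(1, config.n_lnc + 1)],
        "miRNA": [f"MIR{i:04d}" for i in range(1, config.n_mir + 1)],
        "mRNA": [f"MRNA{i:04d}" for i in range(1, config.n_mrna + 1)],
    }


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.Series, GroundTruth]:
    """Simulate the three RNA-class expression matrices plus design and truth.

    Planted axes occupy the first feature of each class per axis.  Each axis
    has a shared per-sample latent factor loading ``+axis_corr`` on the
    lncRNA and mRNA and ``-axis_corr`` on the miRNA; the factor is centered
    within each group so that the planted group difference equals
    ``axis_effect`` standard deviations exactly in expectation.  Responders
    get ``+effect`` on the miRNA and ``-effect`` on lncRNA and mRNA (the
    sponge-depletion direction).  Decoy features are i.i.d. Gaussian noise
    around a feature-specific baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    ids = _feature_ids(config)
    n_r, n_n = config.n_responders, config.n_nonresponders
    n_samples = n_r + n_n
    sample_ids = [f"R{i:02d}" for i in range(1, n_r + 1)] + [
        f"N{i:02d}" for i in range(1, n_n + 1)
    ]
    design = pd.Series(
        [RESPONDER] * n_r + [NONRESPONDER] * n_n, index=sample_ids, name="group"
    )
    group_sign = np.array([1.0] * n_r + [-1.0] * n_n)  # +1 responder, -1 nonresponder

    # within-group sd of an axis member: latent loading plus residual noise
    within_sd = float(np.sqrt(config.axis_corr**2 + config.noise_sd**2))
    shift = config.axis_effect * within_sd  # responder-minus-nonresponder log2 diff

    truth = GroundTruth()
    matrices: dict[str, ExpressionMatrix] = {}
    values = {
        cls: np.empty((len(ids[cls]), n_samples), dtype=float) for cls in ids
    }
    # feature baselines (log2 abundance), drawn per class for reproducible order
    baselines = {
        cls: rng.uniform(6.0, 12.0, size=len(ids[cls])) for cls in ids
    }
    for cls in ids:
        noise = rng.normal(0.0, config.noise_sd, size=values[cls].shape)
        values[cls][:] = baselines[cls][:, None] + noise

    for k in range(config.n_planted_axes):
        lnc, mir, mrna = ids["lncRNA"][k], ids["miRNA"][k], ids["mRNA"][k]
        truth.planted_axes.append((lnc, mir, mrna))
        z = rng.normal(0.0, 1.0, size=n_samples)
        # orthogonalize the latent factor against the group contrast so the
        # planted standardized effect is exact, not confounded by factor noise
        for sign in (1.0, -1.0):
            mask = group_sign == sign
            z[mask] -= z[mask].mean()
        latent = config.axis_corr * z
        half = shift / 2.0
        values["lncRNA"][k] += latent - half * group_sign
        values["mRNA"][k] += latent - half * group_sign
        values["miRNA"][k] += -latent + half * group_sign
        truth.true_group_effects[lnc] = -shift
        truth.true_group_effects[mrna] = -shift
        truth.true_group_effects[mir] = +shift

    for cls in ids:
        matrices[cls] = ExpressionMatrix(
            pd.DataFrame(values[cls], index=ids[cls], columns=sample_ids), cls
        )
    return matrices, design, truth


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[i] for i in rng.integers(0, 4, size=length))


def _has_seed_match(target: str, mir: str) -> bool:
    """>=6mer seed match: target contains the complement of miRNA pos 2-7."""
    return revcomp_rna(mir[1:7]) in target


#: extent of planted complementary pairing (1-based miRNA positions 2..N);
#: the lncRNA site pairs further into the miRNA 3' half than the mRNA site so
#: that the lncRNA wins the alignment-score/free-energy competition
_PAIR_EXTENT_LNC = 16
_PAIR_EXTENT_MRNA = 11


def _planted_site(mir: str, extent: int) -> str:
    """Target-side site sequence: complement of miRNA pos 2..extent, then the
    A opposite miRNA position 1 (canonical 8mer layout at the 3' end)."""
    return revcomp_rna(mir[1:extent]) + "A"


def simulate_sequences(
    config: SyntheticConfig, truth: GroundTruth
) -> dict[str, SequenceSet]:
    """Emit miRNA, lncRNA and mRNA-3'UTR sequences with planted sites.

    Returns a dict with keys ``"miRNA"``, ``"lncRNA"``, ``"mRNA"``.  For every
    planted (miRNA, target) pair the target carries one complementary site
    whose last 8 nt form a canonical 8mer seed match; its coordinates are
    recorded in ``truth.planted_site_positions``.  Decoy targets are
    rejection-sampled to contain no >=6mer seed match to any planted miRNA.
    """
    config.validate()
    # derived stream: independent of the expression draw but still seeded
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    ids = _feature_ids(config)
    planted_mirs = {m for _, m, _ in truth.planted_axes}
    for lnc, mir, mrna in truth.planted_axes:
        for fid, pool in ((lnc, "lncRNA"), (mir, "miRNA"), (mrna, "mRNA")):
            if fid not in ids[pool]:
                raise ValueError(f"planted axis references unknown feature {fid!r}")

    mir_seqs: dict[str, str] = {}
    for mid in ids["miRNA"]:
        mir_seqs[mid] = _random_rna(rng, config.seq_len_mir)

    site_for: dict[str, str] = {}  # target id -> planted site sequence
    for lnc, mir, mrna in truth.planted_axes:
        site_for[lnc] = _planted_site(mir_seqs[mir], _PAIR_EXTENT_LNC)
        site_for[mrna] = _planted_site(mir_seqs[mir], _PAIR_EXTENT_MRNA)

    def make_target(fid: str) -> tuple[str, tuple[int, int] | None]:
        for _ in range(10_000):
            seq = _random_rna(rng, config.seq_len_target)
            pos = None
            if fid in site_for:
                site = site_for[fid]
                if len(site) + 20 > config.seq_len_target:
                    raise ValueError(
                        f"target length {config.seq_len_target} too short to host a "
                        f"{len(site)}-nt site"
                    )
                start = int(
                    rng.integers(20, config.seq_len_target - len(site) - 1)
                )
                seq = seq[:start] + site + seq[start + len(site):]
                # the seed-match (8mer) region is the last 8 nt of the site
                s8 = start + len(site) - 8
                pos = (s8, s8 + 8)
            # reject any target whose background carries a chance >=6mer seed
            # match to a planted miRNA (outside the deliberate site)
            probe = seq if fid not in site_for else seq[: start] + "N" * len(site) + seq[start + len(site):]
            if any(_has_seed_match(probe, mir_seqs[m]) for m in planted_mirs):
                continue
            return seq, pos
        raise RuntimeError(f"rejection sampling failed for target {fid!r}")

    def axis_competes(mir: str, lnc: str, lnc_seq: str, mrna: str, mrna_seq: str) -> bool:
        """Check the planted competition invariant with the package's own
        duplex scoring: the lncRNA site must strictly win on both score and
        free energy at the default retention thresholds."""
        from .containers import SequenceSet as _SS
        from .targets import TARGET_LNC, TARGET_UTR3, predict_targets

        sites = predict_targets(
            _SS({mir: mir_seqs[mir]}), _SS({lnc: lnc_seq}), _SS({mrna: mrna_seq})
        )
        l_rows = sites[sites["target_class"] == TARGET_LNC]
        m_rows = sites[sites["target_class"] == TARGET_UTR3]
        if len(l_rows) != 1 or len(m_rows) != 1:
            return False
        return bool(
            l_rows["align_score"].iloc[0] > m_rows["align_score"].iloc[0]
            and l_rows["dG"].iloc[0] < m_rows["dG"].iloc[0]
        )

    truth.planted_site_positions.clear()
    planted: dict[str, tuple[str, tuple[int, int]]] = {}
    # planted axes first: random flanks inside the alignment window can add
    # chance 3'-pairing, so redraw until the lncRNA site strictly outcompetes
    # the mRNA site (the generator's contract with the downstream screen)
    for lnc, mir, mrna in truth.planted_axes:
        for _ in range(1_000):
            lnc_seq, lnc_pos = make_target(lnc)
            mrna_seq, mrna_pos = make_target(mrna)
            if axis_competes(mir, lnc, lnc_seq, mrna, mrna_seq):
                break
        else:
            raise RuntimeError(
                f"could not realize the site-competition invariant for axis "
                f"({lnc}, {mir}, {mrna})"
            )
        planted[lnc] = (lnc_seq, lnc_pos)
        planted[mrna] = (mrna_seq, mrna_pos)

    def finish(fid: str) -> str:
        if fid in planted:
            seq, pos = planted[fid]
        else:
            seq, pos = make_target(fid)
        if pos is not None:
            truth.planted_site_positions.setdefault(fid, []).append(pos)
        return seq

    lnc_seqs = {fid: finish(fid) for fid in ids["lncRNA"]}
    mrna_seqs = {fid: finish(fid) for fid in ids["mRNA"]}

    for tid, intervals in truth.planted_site_positions.items():
        length = len(lnc_seqs.get(tid) or mrna_seqs[tid])
        for s, e in intervals:
            assert 0 <= s < e <= length

    return {
        "miRNA": SequenceSet(mir_seqs),
        "lncRNA": SequenceSet(lnc_seqs),
        "mRNA": SequenceSet(mrna_seqs),
    }


#: qPCR internal-control genes with group-independent mean Ct
CONTROL_GENES = {"GAPDH": 16.0, "18S": 10.0, "U6": 20.0}
_CT_BASELINE = 40.0


def simulate_qpcr(
    config: SyntheticConfig,
    truth: GroundTruth,
    matrices: dict[str, ExpressionMatrix],
    design: pd.Series,
    ct_noise_sd: float = 0.0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a Ct table (samples x genes) from the simulated cohort.

    Ct = baseline - log2(expression) + noise, so abundant transcripts cross
    threshold earlier.  Internal-control genes (GAPDH, 18S, U6) have
    group-independent means.  By default only the planted-axis genes are
    assayed, mirroring a validation-cohort qPCR panel.
    """
    config.validate()
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    if genes is None:
        genes = [fid for axis in truth.planted_axes for fid in axis]
        if not genes:  # no planted axes: assay the first feature of each class
            genes = [m.features[0] for m in matrices.values()]
    expr = pd.concat([m.values for m in matrices.values()])
    samples = list(design.index)
    data = {}
    for g in genes:
        if g not in expr.index:
            raise KeyError(f"gene {g!r} not in the simulated matrices")
        data[g] = _CT_BASELINE - expr.loc[g, samples].to_numpy(dtype=float)
    for ctrl, mean_ct in CONTROL_GENES.items():
        data[ctrl] = np.full(len(samples), mean_ct)
    ct = pd.DataFrame(data, index=pd.Index(samples, name="sample"))
    if ct_noise_sd > 0:
        ct += rng.normal(0.0, ct_noise_sd, size=ct.shape)
    return ct
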