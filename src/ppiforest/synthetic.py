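"""Synthetic PSSMs and planted-interaction pair datasets.

Stands in for benchmark PPI collections so the whole pipeline is testable
offline.  Each protein carries a latent vector z ~ N(0, I_q); its PSSM rows
are integer log-odds scores whose column means are tilted by a fixed affine
image of z, so proteins with similar latents have similar residue profiles.
Interacting pairs are planted by latent similarity: an unordered pair (i, j)
is drawn as positive with weight exp(link_gain * separation * z_i . z_j)
(sampled without replacement via Gumbel top-k), so ``separation = 0`` yields
a label-free null, and larger values concentrate positives on
high-inner-product pairs with an essentially deterministic rule at
``separation = 4``.

Defaults emulate benchmark scale: integer scores clipped to [-10, 12]
(PSI-BLAST log-odds magnitudes, so the logistic squashing in the feature
stage operates in its realistic regime), chain lengths 50-200 residues, a
1-dimensional latent similarity axis, tilt scale 3 and residue noise sd 2.

All randomness flows from ``config.seed`` through per-stage child
generators; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from ppiforest.pssm_io import (
    AA_ORDER,
    PSSM,
    PairList,
    PairRecord,
    ProteinSequence,
    ValidationError,
    write_ascii_pssm,
    write_fasta,
    write_pair_list,
)

SCORE_MIN = -10
SCORE_MAX = 12


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic PPI benchmark generator.

    separation is the class-signal strength: 0 plants no signal (null data),
    4 plants a strong, recoverable signal.  tilt_scale and noise_sd control
    how strongly the latent vector shapes PSSM column means relative to
    per-entry noise, on the integer log-odds scale.
    """

    n_proteins: int = 120
    length_range: tuple[int, int] = (50, 200)
    latent_dim: int = 1
    separation: float = 1.0
    n_pos_pairs: int = 200
    n_neg_pairs: int = 200
    seed: int = 0
    tilt_scale: float = 3.0
    noise_sd: float = 2.0
    link_gain: float = 3.0
    #: cohort index: configs sharing a seed but differing in cohort draw
    #: fresh proteins under the SAME latent-to-profile map, emulating
    #: independent datasets from one conserved interaction system
    cohort: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid length_range {self.length_range}")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.n_pos_pairs < 1 or self.n_neg_pairs < 1:
            raise ValidationError("pair counts must be >= 1")
        n_avail = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_pos_pairs + self.n_neg_pairs > n_avail:
            raise ValidationError(
                f"requested {self.n_pos_pairs + self.n_neg_pairs} pairs but only "
                f"{n_avail} distinct unordered pairs exist"
            )


def _rng(config: SyntheticConfig, stream: int, per_cohort: bool = True) -> np.random.Generator:
    # independent child stream per stage, all rooted at config.seed; the
    # latent-to-profile map ignores the cohort so cohorts are comparable
    key = [int(config.seed), stream]
    if per_cohort:
        key.append(int(config.cohort))
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_proteins(
    config: SyntheticConfig,
) -> tuple[list[ProteinSequence], list[PSSM], np.ndarray]:
    """Draw proteins, their PSSMs, and the latent matrix (n x latent_dim).

    Column means of protein i's score rows are tilted by
    ``tilt_scale * (z_i @ B) / sqrt(latent_dim)`` with a fixed random mixing
    matrix B, then integer noise is added and scores are clipped to
    [-10, 12].  Sequences take each position's argmax-score residue, so
    sequence composition is consistent with the profile.
    """
    config.validate()
    n, q = config.n_proteins, config.latent_dim
    mixing = _rng(config, 0, per_cohort=False).standard_normal((q, 20))
    rng = _rng(config, 1)
    latents = rng.standard_normal((n, q))
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    proteins: list[ProteinSequence] = []
    pssms: list[PSSM] = []
    width = max(4, len(str(n)))
    for i in range(n):
        tilt = config.tilt_scale * (latents[i] @ mixing) / np.sqrt(q)
        raw = tilt[None, :] + rng.normal(0.0, config.noise_sd, size=(lengths[i], 20))
        scores = np.clip(np.rint(raw), SCORE_MIN, SCORE_MAX)
        pid = f"P{i:0{width}d}"
        residues = "".join(AA_ORDER[j] for j in np.argmax(scores, axis=1))
        proteins.append(ProteinSequence(id=pid, residues=residues))
        pssms.append(PSSM(protein_id=pid, scores=scores))
    return proteins, pssms, latents


def generate_pairs(latents: np.ndarray, config: SyntheticConfig) -> PairList:
    """Plant positive pairs by latent similarity and sample uniform negatives.

    Positives: n_pos_pairs unordered pairs drawn without replacement with
    weight sigma(separation * z_i . z_j) (Gumbel top-k).  Negatives:
    n_neg_pairs uniform draws from the remaining pairs.  No unordered pair
    appears twice.
    """
    config.validate()
    rng = _rng(config, 2)
    n = latents.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    sim = np.einsum("ij,ij->i", latents[iu], latents[ju])
    # exponential tilt toward aligned latents; link_gain sets how sharply a
    # unit of separation concentrates positives on high-similarity pairs
    logw = config.link_gain * config.separation * sim
    n_all = iu.size
    if config.n_pos_pairs + config.n_neg_pairs > n_all:
        raise ValidationError("requested more pairs than available")

    gumbel = rng.gumbel(size=n_all)
    pos_idx = np.argpartition(-(logw + gumbel), config.n_pos_pairs - 1)[
        : config.n_pos_pairs
    ]
    pos_set = set(pos_idx.tolist())
    remaining = np.array([k for k in range(n_all) if k not in pos_set])
    neg_idx = rng.choice(remaining, size=config.n_neg_pairs, replace=False)

    width = max(4, len(str(n)))

    def pid(k: int) -> str:
        return f"P{k:0{width}d}"

    records = [
        PairRecord(id_a=pid(iu[k]), id_b=pid(ju[k]), label=1)
        for k in sorted(pos_idx.tolist())
    ]
    records += [
        PairRecord(id_a=pid(iu[k]), id_b=pid(ju[k]), label=0)
        for k in sorted(neg_idx.tolist())
    ]
    return PairList(records=records)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ProteinSequence], list[PSSM], PairList, np.ndarray]:
    """Convenience wrapper: proteins + PSSMs + planted pair labels."""
    proteins, pssms, latents = generate_proteins(config)
    pairs = generate_pairs(latents, config)
    return proteins, pssms, pairs, latents


def write_fixture(
    directory: str | Path,
    proteins: list[ProteinSequence],
    pssms: list[PSSM],
    pairs: PairList,
    config: SyntheticConfig | None = None,
) -> Path:
    """Write a dataset to disk in the formats the readers consume.

    Layout: ``proteins.fasta``, ``pssm/<id>.pssm``, ``pairs.tsv`` and a
    ``manifest.json`` listing the files and (when given) the generating
    config.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pssm_dir = directory / "pssm"
    pssm_dir.mkdir(exist_ok=True)

    fasta_path = directory / "proteins.fasta"
    write_fasta(fasta_path, proteins)
    residues = {p.id: p.residues for p in proteins}
    pssm_files = []
    for p in pssms:
        f = pssm_dir / f"{p.protein_id}.pssm"
        write_ascii_pssm(f, p, residues=residues.get(p.protein_id))
        pssm_files.append(str(f.relative_to(directory)))
    pairs_path = directory / "pairs.tsv"
    write_pair_list(pairs_path, pairs)

    manifest = {
        "fasta": fasta_path.name,
        "pairs": pairs_path.name,
        "pssm_files": pssm_files,
        "n_proteins": len(proteins),
        "n_pairs": len(pairs),
        "config": asdict(config) if config is not None else None,
    }
    if manifest["config"] is not None:
        manifest["config"]["length_range"] = list(config.length_range)
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
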