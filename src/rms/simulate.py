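"""Synthetic RiboMethSeq data with known ground truth.

The generator emulates the statistical structure the scores rely on,
without modeling sequence chemistry:

* heterogeneous alkaline cleavage — each phosphodiester bond carries an
  i.i.d. log-normal propensity with unit mean (``cleavage_sigma`` is the
  s.d. of the log; 0 gives a perfectly homogeneous profile);
* Nm protection — a site methylated in fraction ``m`` of molecules with
  protection efficiency ``pi`` suppresses the expected cleavage of its
  3'-adjacent bond by ``m * pi``;
* pseudouridine ligation bias — a modified 5'-terminal nucleotide
  ligates poorly, removing a fraction ``ligation_bias`` of the 5'-end
  counts that register at the annotated position and creating an
  Nm-like false-positive gap;
* Poisson counting noise on every 5'- and 3'-end count, with only a
  fraction ``ratio_3p`` of fragments short enough to pass the 3'-end
  length filter.

Identical configurations (including the mandatory seed) give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from rms.profiles import DEFAULT_MAX_LEN_3P, EndCountProfile
from rms.scoring import ScoreParams, methscore
from rms.evaluation import SiteAnnotation


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated RiboMethSeq library.

    Attributes
    ----------
    ref_length : int
        Reference length in nucleotides.
    coverage : float
        Expected 5'-end count per position before modification effects.
    cleavage_sigma : float
        S.d. of the log-normal per-bond cleavage propensity (unit mean).
    nm_sites : tuple of (pos, m)
        1-based Nm positions with methylation fraction ``m`` in [0, 1].
    protection : float
        Fraction of cleavage suppressed at a fully methylated bond.
    psi_sites : tuple of int
        1-based pseudouridine positions.
    ligation_bias : float
        Fractional loss of the 5'-end counts registering at a
        pseudouridine position.
    ratio_3p : float
        Fraction of fragments short enough to contribute 3'-end counts.
    seed : int
        Mandatory RNG seed; identical configs reproduce bit-identically.
    """

    ref_length: int
    seed: int
    coverage: float = 1000.0
    cleavage_sigma: float = 0.3
    nm_sites: tuple[tuple[int, float], ...] = ()
    protection: float = 1.0
    psi_sites: tuple[int, ...] = ()
    ligation_bias: float = 0.5
    ratio_3p: float = 0.4
    ref_name: str = "sim_rRNA"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "nm_sites", tuple((int(p), float(m)) for p, m in self.nm_sites)
        )
        object.__setattr__(self, "psi_sites", tuple(int(p) for p in self.psi_sites))
        problems = []
        if self.ref_length <= 0:
            problems.append(f"ref_length={self.ref_length} (must be > 0)")
        if self.coverage <= 0:
            problems.append(f"coverage={self.coverage} (must be > 0)")
        if self.cleavage_sigma < 0:
            problems.append(f"cleavage_sigma={self.cleavage_sigma} (must be >= 0)")
        for name, value in [
            ("protection", self.protection),
            ("ligation_bias", self.ligation_bias),
            ("ratio_3p", self.ratio_3p),
        ]:
            if not 0 <= value <= 1:
                problems.append(f"{name}={value} (must be in [0, 1])")
        for pos, m in self.nm_sites:
            if not 1 <= pos <= self.ref_length:
                problems.append(f"nm site position {pos} outside [1, {self.ref_length}]")
            if not 0 <= m <= 1:
                problems.append(f"methylation fraction {m} at position {pos}")
        for pos in self.psi_sites:
            if not 1 <= pos <= self.ref_length:
                problems.append(f"psi position {pos} outside [1, {self.ref_length}]")
        overlap = {p for p, _ in self.nm_sites} & set(self.psi_sites)
        if overlap:
            problems.append(f"positions annotated both Nm and psi: {sorted(overlap)}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def annotation(self) -> SiteAnnotation:
        rows = [(self.ref_name, p, "Nm") for p, _ in self.nm_sites]
        rows += [(self.ref_name, p, "psi") for p in self.psi_sites]
        return SiteAnnotation(
            pd.DataFrame(rows, columns=["ref", "pos", "status"])
        )


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    config: SimConfig
    cleavage: np.ndarray  # per-bond propensity c_b, bonds 0..ref_length
    annotation: SiteAnnotation
    methylation: dict[int, float]  # position -> fraction m


def _bond_intensities(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expected 5'-end count per bond b = 0..L (bond b is 3' of nucleotide b)."""
    L = config.ref_length
    sigma = config.cleavage_sigma
    if sigma > 0:
        c = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=L + 1)
    else:
        c = np.ones(L + 1)
    m = np.zeros(L + 1)
    for pos, frac in config.nm_sites:
        m[pos] = frac
    lam = config.coverage * c * (1.0 - m * config.protection)
    return lam, c


def simulate_profile(config: SimConfig) -> tuple[EndCountProfile, SimTruth]:
    """Draw an end-count profile under the configured generative model.

    The 5'-end count at position ``p`` is Poisson with mean equal to the
    intensity of bond ``p - 1``, scaled by ``1 - ligation_bias`` when the
    combined count it feeds belongs to a pseudouridine position; the
    3'-end count at ``p`` is Poisson with mean ``ratio_3p`` times the
    intensity of bond ``p``.
    """
    rng = np.random.default_rng(config.seed)
    lam, c = _bond_intensities(config, rng)
    L = config.ref_length
    # count5[p] reports bond p-1 (0-based array index i = p-1)
    mean5 = lam[:L].copy()
    for pos in config.psi_sites:
        # deplete the 5'-end component of the combined count at the psi
        # position itself: count5[pos + 1] reports bond pos
        if pos + 1 <= L:
            mean5[pos] *= 1.0 - config.ligation_bias
    mean3 = config.ratio_3p * lam[1 : L + 1]
    count5 = rng.poisson(mean5)
    count3 = rng.poisson(mean3)
    profile = EndCountProfile(
        ref_name=config.ref_name,
        count5=count5,
        count3=count3,
        n_reads_counted=int(count5.sum()),
    )
    truth = SimTruth(
        config=config,
        cleavage=c,
        annotation=config.annotation(),
        methylation=dict(config.nm_sites),
    )
    return profile, truth


def random_reference(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGU"), size=length)).replace("U", "T")


@dataclass
class SimReads:
    """Output bundle of :func:`simulate_reads`."""

    sam_path: Path
    fasta_path: Path
    truth: SimTruth
    n_reads: int
    expected: EndCountProfile  # the profile count_ends must recover


def simulate_reads(
    config: SimConfig,
    out_dir,
    read_length_range: tuple[int, int] = (20, 59),
    max_len_3p: int = DEFAULT_MAX_LEN_3P,
) -> SimReads:
    """Emit aligned reads (SAM + reference FASTA) with known end counts.

    Fragment 5'-ends are drawn per-bond exactly as in
    :func:`simulate_profile`; each read gets a uniform length in
    ``read_length_range``. Drawn fragments that would run past the
    reference are discarded — their 3'-end would be the molecule's native
    terminus, not a cleavage bond — so coverage tapers over the last
    read-length's worth of positions. Alignments are written directly
    (perfect matches, forward strand), so re-counting them with
    ``count_ends`` recovers the intended counts exactly; no external
    aligner is involved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    lam, c = _bond_intensities(config, rng)
    L = config.ref_length
    mean5 = lam[:L].copy()
    for pos in config.psi_sites:
        if pos + 1 <= L:
            mean5[pos] *= 1.0 - config.ligation_bias
    starts_per_pos = rng.poisson(mean5)  # index i -> reads starting at pos i+1

    seq = random_reference(L, config.seed)
    fasta_path = out_dir / f"{config.ref_name}.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(f">{config.ref_name}\n")
        for i in range(0, L, 60):
            fh.write(seq[i : i + 60] + "\n")

    count5 = np.zeros(L, dtype=np.int64)
    count3 = np.zeros(L, dtype=np.int64)
    lo, hi = read_length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid read_length_range {read_length_range}")
    sam_path = out_dir / f"{config.ref_name}.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.ref_name, "LN": L}],
    }
    n_reads = 0
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for i in range(L):
            k = int(starts_per_pos[i])
            if k == 0:
                continue
            lengths = rng.integers(lo, hi + 1, size=k)
            for ell in lengths:
                start0 = i  # 0-based
                alen = int(ell)
                if start0 + alen > L:
                    continue  # fragment would end at the native 3' terminus
                end0 = start0 + alen - 1
                rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                rec.query_name = f"sim_{n_reads}"
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = start0
                rec.mapping_quality = 60
                rec.cigarstring = f"{alen}M"
                rec.query_sequence = seq[start0 : end0 + 1]
                sam.write(rec)
                count5[start0] += 1
                if alen < max_len_3p:
                    count3[end0] += 1
                n_reads += 1
    expected = EndCountProfile(
        ref_name=config.ref_name,
        count5=count5,
        count3=count3,
        n_reads_counted=n_reads,
    )
    truth = SimTruth(
        config=config,
        cleavage=c,
        annotation=config.annotation(),
        methylation=dict(config.nm_sites),
    )
    return SimReads(
        sam_path=sam_path,
        fasta_path=fasta_path,
        truth=truth,
        n_reads=n_reads,
        expected=expected,
    )


def recovery_experiment(
    m_grid: Sequence[float],
    n_seeds: int = 50,
    seed: int = 0,
    coverage: float = 1000.0,
    protection: float = 1.0,
    cleavage_sigma: float = 0.0,
    ratio_3p: float = 0.4,
    ref_length: int = 41,
    params: ScoreParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Measure how well MethScore recovers the true methylation fraction.

    One Nm site is placed mid-reference; for each ``m`` on the grid the
    site's MethScore is averaged over ``n_seeds`` independent libraries.
    Under full protection and homogeneous cleavage the expectation is
    exactly ``m``, so the linear fit of mean score on ``m`` should have
    slope ~1 and intercept ~0.

    Returns the per-``m`` summary table and the linear-fit parameters
    (slope, intercept, Pearson r).
    """
    params = params or ScoreParams(window=2)
    site = ref_length // 2 + 1
    master = np.random.default_rng(seed)
    sim_seeds = master.integers(0, 2**31 - 1, size=(len(m_grid), n_seeds))
    rows = []
    for gi, m in enumerate(m_grid):
        values = []
        for si in range(n_seeds):
            config = SimConfig(
                ref_length=ref_length,
                seed=int(sim_seeds[gi, si]),
                coverage=coverage,
                cleavage_sigma=cleavage_sigma,
                nm_sites=((site, float(m)),),
                protection=protection,
                ratio_3p=ratio_3p,
            )
            profile, _ = simulate_profile(config)
            track = methscore(profile, params)
            if not track.valid[site - 1]:
                continue
            values.append(track.values[site - 1])
        values = np.asarray(values)
        rows.append(
            {
                "m": float(m),
                "mean_score": float(values.mean()),
                "sd_score": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                "bias": float(values.mean() - m),
                "n_seeds": len(values),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        fit = stats.linregress(table["m"], table["mean_score"])
        fit_summary = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r": float(fit.rvalue),
        }
    else:
        fit_summary = {"slope": float("nan"), "intercept": float("nan"), "r": float("nan")}
    return table, fit_summary
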