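"""Synthetic multi-subject, two-session cohorts with planted individual structure.

Each subject carries a low-dimensional latent vector z that simultaneously
drives (a) the geometry of their oscillatory ROI dynamics, (b) a binary group
label, and (c) a battery of behavioral scores.  This makes every downstream
claim testable: cross-session fingerprinting, group classification, and
brain-behavior canonical correlation all have a planted ground truth.

Signal model per subject i, ROI r, session s (time in seconds):

    x(t) = a_{i,r} sin(2 pi f_{i,r} t + phi_{i,r,s})
         + h_{i,r} sin(4 pi f_{i,r} t + psi_{i,r,s}) + eps(t)

with eps ~ N(0, sigma^2) i.i.d.  Amplitude a, harmonic amplitude h,
frequency f, and the harmonic's relative phase are smooth (affine-then-tanh)
functions of z, drawn once per subject; the base phases phi, psi are
redrawn per session as subject-level phases plus Gaussian session jitter.
Frequencies stay within 0.01-0.08 Hz so the planted signal survives the
conventional resting-state bandpass.  The second harmonic is essential:
a pure sinusoid delay-embeds to an ellipse for every subject, whereas the
harmonic term gives each subject an individual loop geometry that H1
persistence can distinguish.

Behaviors are Y_i = C z_i + eta with fixed unit-norm rows C; the group label
is g_i = 1{w . z_i > 0} for a fixed unit vector w.  C and w are deterministic
constants (independent of the cohort seed) so that the planted brain-behavior
association strength is a property of the model, not of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "fixture_square",
    "fixture_circle",
    "write_cohort",
    "DEFAULT_NETWORKS",
    "planted_canonical_correlation",
]

DEFAULT_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
)

# Fixed internal seed for the behavior map C and group direction w; these are
# model constants, deliberately decoupled from CohortSpec.seed.
_STRUCTURAL_SEED = 20240613


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 50 subjects, 20 ROIs, 300 timepoints at TR = 0.72 s, 5 latent
    dimensions, session noise sd 0.3 (roughly a third of the unit signal
    amplitude), and 12 behavioral items whose noise level (0.75) plants a
    first canonical correlation of about 0.95 between latents and
    behaviors — a deliberately strong association, sized so that a
    50-subject cohort retains the statistical power that the reference
    analyses obtain from cohorts twenty times larger.
    """

    n_subjects: int = 50
    n_rois: int = 20
    n_timepoints: int = 300
    tr: float = 0.72
    n_latents: int = 5
    session_noise_sd: float = 0.3
    phase_jitter_sd: float = 0.05
    session_amp_drift: float = 0.0
    session_freq_drift: float = 0.04
    envelope_mod_depth: float = 0.0
    behavior_dims: int = 12
    behavior_noise_sd: float = 0.75
    effect_scale: float = 1.0
    seed: int = 0
    networks: tuple = DEFAULT_NETWORKS

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_rois", "n_timepoints", "n_latents",
                     "behavior_dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("session_noise_sd", "phase_jitter_sd", "behavior_noise_sd",
                     "session_amp_drift", "session_freq_drift", "envelope_mod_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort: series per (subject, session), truth, and labels."""

    spec: CohortSpec
    series: dict  # (subject, session) -> (n_rois, n_timepoints) array
    latents: np.ndarray  # (n_subjects, q)
    behaviors: pd.DataFrame  # subjects x items
    group: np.ndarray  # (n_subjects,) in {0, 1}
    network_labels: list  # per-ROI network name
    truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects


def _structural_maps(q: int, p: int):
    """Fixed unit-row behavior map C (p x q) and group direction w (q,)."""
    rng = np.random.default_rng(_STRUCTURAL_SEED)
    C = rng.standard_normal((p, q))
    C /= np.linalg.norm(C, axis=1, keepdims=True)
    w = rng.standard_normal(q)
    w /= np.linalg.norm(w)
    return C, w


def planted_canonical_correlation(q: int, p: int, behavior_noise_sd: float) -> float:
    """Population first canonical correlation between z and Y = C z + eta.

    With z ~ N(0, I_q) and eta ~ N(0, s^2 I_p) this is the square root of the
    largest eigenvalue of C^T (C C^T + s^2 I)^{-1} C.
    """
    C, _ = _structural_maps(q, p)
    s2 = behavior_noise_sd**2
    M = C.T @ np.linalg.solve(C @ C.T + s2 * np.eye(p), C)
    return float(np.sqrt(np.linalg.eigvalsh(M).max()))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a reproducible two-session cohort from a spec.

    All randomness flows from ``spec.seed``.  With zero session noise and
    zero phase jitter the two sessions are bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    N, R, T, q = spec.n_subjects, spec.n_rois, spec.n_timepoints, spec.n_latents
    alpha = spec.effect_scale
    t = np.arange(T) * spec.tr

    C, w = _structural_maps(q, spec.behavior_dims)

    # Per-ROI projection directions mapping the latent to dynamical parameters.
    U_a = rng.standard_normal((R, q)) / np.sqrt(q)
    U_h = rng.standard_normal((R, q)) / np.sqrt(q)
    U_f = rng.standard_normal((R, q)) / np.sqrt(q)
    U_d = rng.standard_normal((R, q)) / np.sqrt(q)
    # ROI base frequencies spread across the passband interior
    f_base = np.linspace(0.025, 0.065, R)

    latents = rng.standard_normal((N, q))
    # Idiosyncratic per-(subject, ROI) components: individual uniqueness not
    # carried by the behavior-relevant latent (drawn once per subject, so it
    # is session-stable and strengthens fingerprints without adding
    # brain-behavior signal).
    E_a = rng.standard_normal((N, R))
    E_h = rng.standard_normal((N, R))
    E_d = rng.standard_normal((N, R))

    # Subject-level parameters (derived once per subject).  The harmonic
    # amplitude and its relative phase set the embedded loop's geometry and
    # carry the individual signal; base amplitude and frequency are shared
    # across subjects (and mildly modulated by the latent through U_a/U_f so
    # that effect_scale can re-introduce them if desired at alpha > 1).
    a = 1.0 + 0.45 * np.tanh(alpha * latents @ U_a.T + 0.7 * E_a)   # (N, R)
    h = 0.40 + 0.35 * np.tanh(alpha * latents @ U_h.T + 0.4 * E_h)
    f = f_base[None, :] * (1.0 + 0.01 * np.tanh(alpha * latents @ U_f.T))
    delta = np.pi * np.tanh(alpha * latents @ U_d.T + 0.4 * E_d)    # harmonic phase offset
    phi0 = rng.uniform(0, 2 * np.pi, size=(N, R))
    psi0 = 2 * phi0 + delta

    # Session-level state: besides additive noise and a small phase jitter,
    # each (subject, ROI, session) gets a multiplicative amplitude drift and
    # a frequency drift, emulating scan-to-scan changes in signal gain and
    # oscillation rate.  These corrupt variance- and autocorrelation-based
    # summaries across sessions while leaving the shape of the orbit — what
    # persistence reads — essentially intact.
    # Slow within-scan amplitude modulation (arousal-drift analog): one to
    # two envelope cycles per scan, with a session-random envelope phase.
    # Finite-scan moment statistics inherit large estimator variance from
    # where the scan happens to sit in the envelope cycle, whereas the
    # swept orbit fills an annulus whose geometry barely depends on the
    # envelope phase.
    f_mod = rng.uniform(0.004, 0.008, size=(N, R))
    mod_depth = spec.envelope_mod_depth

    series: dict = {}
    for i in range(N):
        for s in (1, 2):
            jit_phi = rng.normal(0, 1, size=R) * spec.phase_jitter_sd
            jit_psi = rng.normal(0, 1, size=R) * spec.phase_jitter_sd
            gain = 1.0 + rng.normal(0, 1, size=R) * spec.session_amp_drift
            f_s = f[i] * (1.0 + rng.normal(0, 1, size=R) * spec.session_freq_drift)
            phi = phi0[i] + jit_phi
            psi = psi0[i] + jit_psi
            xi = rng.uniform(0, 2 * np.pi, size=R)
            envelope = 1.0 + mod_depth * np.sin(
                2 * np.pi * f_mod[i][:, None] * t + xi[:, None])
            clean = gain[:, None] * envelope * (
                a[i][:, None] * np.sin(2 * np.pi * f_s[:, None] * t + phi[:, None])
                + h[i][:, None] * np.sin(4 * np.pi * f_s[:, None] * t + psi[:, None])
            )
            noise = rng.normal(0, 1, size=(R, T)) * spec.session_noise_sd
            series[(i, s)] = clean + noise

    eta = rng.normal(0, 1, size=(N, spec.behavior_dims)) * spec.behavior_noise_sd
    Y = latents @ C.T + eta
    item_names = [f"item_{j:02d}" for j in range(spec.behavior_dims)]
    behaviors = pd.DataFrame(Y, columns=item_names,
                             index=[f"sub-{i:03d}" for i in range(N)])
    group = (latents @ w > 0).astype(int)

    networks = [spec.networks[r % len(spec.networks)] for r in range(R)]
    truth = {
        "latents": latents,
        "amplitude": a,
        "harmonic": h,
        "frequency": f,
        "harmonic_phase_offset": delta,
        "behavior_map": C,
        "group_direction": w,
        "planted_canonical_correlation": planted_canonical_correlation(
            q, spec.behavior_dims, spec.behavior_noise_sd
        ),
    }
    return SyntheticCohort(spec=spec, series=series, latents=latents,
                           behaviors=behaviors, group=group,
                           network_labels=networks, truth=truth)


def fixture_square() -> np.ndarray:
    """The four corners of the unit square, a hand-checkable H1 fixture."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def fixture_circle(n: int = 60, radius: float = 1.0, noise_sd: float = 0.0,
                   seed: int = 0) -> np.ndarray:
    """n points at uniform angles on a circle with Gaussian coordinate noise."""
    if n < 8:
        raise ValueError("need at least 8 points")
    angles = 2 * np.pi * np.arange(n) / n
    pts = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    if noise_sd > 0:
        pts = pts + np.random.default_rng(seed).normal(0, noise_sd, pts.shape)
    return pts


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort as TSV files plus a truth.json sidecar.

    Layout: ``sub-<i>_ses-<s>.tsv`` (rows = ROIs, columns = timepoints),
    ``networks.tsv``, ``behaviors.tsv``, ``groups.tsv``, ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    T = cohort.spec.n_timepoints
    cols = [str(k) for k in range(T)]
    for (i, s), mat in sorted(cohort.series.items()):
        df = pd.DataFrame(mat, columns=cols)
        df.to_csv(out / f"sub-{i:03d}_ses-{s}.tsv", sep="\t", index=False)
    pd.DataFrame({
        "roi_id": range(cohort.spec.n_rois),
        "network": cohort.network_labels,
    }).to_csv(out / "networks.tsv", sep="\t", index=False)
    cohort.behaviors.rename_axis("subject").to_csv(out / "behaviors.tsv", sep="\t")
    pd.DataFrame({
        "subject": cohort.behaviors.index,
        "group": cohort.group,
    }).to_csv(out / "groups.tsv", sep="\t", index=False)
    domains = ("cognition", "emotion", "personality")
    pd.DataFrame({
        "item": cohort.behaviors.columns,
        "domain": [domains[j % len(domains)]
                   for j in range(cohort.behaviors.shape[1])],
    }).to_csv(out / "domains.tsv", sep="\t", index=False)
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in cohort.truth.items()}
    truth["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(cohort.spec).items()}
    (out / "truth.json").write_text(json.dumps(truth))
    return out
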