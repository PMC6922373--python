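"""Indel-spectrum estimation from a bulk Sanger trace by constrained regression.

A sample chromatogram from an edited cell pool is a superposition of the
wild-type trace and copies of it shifted by each allele's indel size
downstream of the cut. The model regresses the sample's per-base channel
intensities, over a decomposition window downstream of the cut site, onto
candidate component profiles built by shifting the control (wild-type)
trace by every indel size in ``[-max_indel, +max_indel]``, under
non-negativity constraints (NNLS). Component weights normalize to allele
frequencies; per-component significance comes from an unconstrained
ordinary-least-squares refit restricted to the active (non-zero) set; the
overall fit quality R^2 gates the result (wells below ``min_r2`` are
eliminated as unreliable).

Usage follows the fit/results pattern::

    model = TraceDecomposition(sample, control, reference)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Chromatogram, ReferenceAmplicon

__all__ = [
    "DecompositionSettings",
    "ComponentProfile",
    "TraceDecomposition",
    "TraceDecompositionResults",
    "align_control",
    "build_components",
    "decompose",
    "overall_efficiency",
    "RegistrationError",
    "UnderdeterminedError",
]


class RegistrationError(RuntimeError):
    """Sample and control traces could not be registered (likely mismatch)."""


class UnderdeterminedError(ValueError):
    """Decomposition window too small for the candidate component count."""


@dataclass(frozen=True)
class DecompositionSettings:
    """Tuning parameters of the trace decomposition.

    Defaults follow common decomposition practice for a ~500 bp amplicon
    read: candidate indels of 1-30 bp in either direction, a decomposition
    window of trace positions [115, 500), a 100 bp upstream alignment
    window for sample/control registration, a p < 1e-4 significance cutoff
    for reported components, and elimination of fits with R^2 < 0.95.
    ``min_report_freq`` (percent) suppresses numerically tiny components.
    """

    max_indel: int = 30
    decomposition_window: tuple[int, int] = (115, 500)
    alignment_window: int = 100
    p_cutoff: float = 1e-4
    min_r2: float = 0.95
    min_report_freq: float = 0.5
    max_shift: int = 10
    min_alignment_corr: float = 0.5

    def __post_init__(self) -> None:
        w0, w1 = self.decomposition_window
        if w0 <= 0 or w1 <= w0:
            raise ValueError("decomposition_window must be (start>0, end>start)")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if not 0 < self.min_r2 <= 1:
            raise ValueError("min_r2 must be in (0, 1]")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")


@dataclass(frozen=True)
class ComponentProfile:
    """Expected trace of one candidate indel over the decomposition window.

    For a deletion of d bp the post-cut trace is the control advanced by d
    positions; for an insertion it is the control delayed by d, with the d
    novel positions at the cut masked (the control carries no information
    about inserted bases). ``profile`` has shape (len(positions), 4).
    """

    indel_size: int
    positions: np.ndarray
    profile: np.ndarray
    masked_positions: frozenset[int] = field(default_factory=frozenset)


def align_control(
    sample: Chromatogram,
    control: Chromatogram,
    settings: DecompositionSettings | None = None,
) -> int:
    """Register sample to control over the upstream alignment window.

    Returns the integer shift s in [-max_shift, max_shift] maximizing the
    channel-wise Pearson correlation between ``sample[i]`` and
    ``control[i + s]`` over the first ``alignment_window`` positions (a
    region upstream of the cut where all alleles agree with wild type).

    Raises
    ------
    RegistrationError
        If the best correlation falls below ``min_alignment_corr``,
        indicating a sample/control mismatch.
    """
    settings = settings or DecompositionSettings()
    w = settings.alignment_window
    need = w + settings.max_shift
    if len(sample) < need or len(control) < need:
        raise ValueError("traces shorter than alignment window plus max shift")
    best_shift, best_corr = 0, -np.inf
    for shift in range(-settings.max_shift, settings.max_shift + 1):
        s0, c0 = max(0, -shift), max(0, shift)
        s_win = sample.channels[s0 : s0 + w].ravel()
        c_win = control.channels[c0 : c0 + w].ravel()
        ss, cs = s_win - s_win.mean(), c_win - c_win.mean()
        denom = np.linalg.norm(ss) * np.linalg.norm(cs)
        corr = float(ss @ cs / denom) if denom > 0 else 0.0
        if corr > best_corr:
            best_corr, best_shift = corr, shift
    if best_corr < settings.min_alignment_corr:
        raise RegistrationError(
            f"best alignment correlation {best_corr:.3f} below "
            f"{settings.min_alignment_corr}; sample/control mismatch?"
        )
    return best_shift


def build_components(
    control: Chromatogram,
    cut_site: int,
    settings: DecompositionSettings | None = None,
) -> list[ComponentProfile]:
    """Shift the control trace by every candidate indel size.

    The window is the configured decomposition window intersected with
    ``[cut_site, len(control))`` — only post-cut signal carries indel
    information. A deletion of d bp maps window position p to control
    position p + d; an insertion maps p to control position p - d and masks
    the d inserted positions ``[cut_site, cut_site + d)``.
    """
    settings = settings or DecompositionSettings()
    w0, w1 = settings.decomposition_window
    w0 = max(w0, cut_site)
    if w1 <= w0:
        raise ValueError("decomposition window empty after clipping to the cut site")
    if w1 + settings.max_indel > len(control):
        raise ValueError(
            f"decomposition window [{w0}, {w1}) extends past the shifted control "
            f"(control length {len(control)}, max shift {settings.max_indel})"
        )
    positions = np.arange(w0, w1)
    comps = []
    for d in range(-settings.max_indel, settings.max_indel + 1):
        if d < 0:
            src = positions + (-d)
            masked: frozenset[int] = frozenset()
        elif d > 0:
            src = positions - d
            masked = frozenset(range(cut_site, cut_site + d))
        else:
            src = positions
            masked = frozenset()
        if src.min() < 0 or src.max() >= len(control):
            raise ValueError(f"window extends past control trace for indel {d}")
        comps.append(
            ComponentProfile(
                indel_size=d,
                positions=positions,
                profile=control.channels[src],
                masked_positions=masked,
            )
        )
    return comps


class TraceDecomposition:
    """NNLS decomposition of a sample trace against a wild-type control.

    Parameters
    ----------
    sample, control : Chromatogram
        Edited-pool and wild-type traces of the same amplicon.
    reference : ReferenceAmplicon
        Supplies the cut-site coordinate (and sanity context).
    settings : DecompositionSettings, optional
    """

    def __init__(
        self,
        sample: Chromatogram,
        control: Chromatogram,
        reference: ReferenceAmplicon,
        settings: DecompositionSettings | None = None,
    ) -> None:
        self.sample = sample
        self.control = control
        self.reference = reference
        self.settings = settings or DecompositionSettings()

    # -- internal -----------------------------------------------------------

    def _design(self, offset: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Build (X, y, sizes) over the unmasked cells of the window.

        The registration offset is absorbed by re-indexing the sample;
        insertion components leave their novel positions undefined, so the
        union of all candidate insertion masks — window positions
        ``[cut_site, cut_site + max_indel)`` — is excluded for every
        component, giving one shared cell set for the joint regression.
        """
        st = self.settings
        cut = self.reference.cut_site
        comps = build_components(self.control, cut, st)
        positions = comps[0].positions
        union_mask = frozenset(range(cut, cut + st.max_indel))
        keep = np.array([p not in union_mask for p in positions])
        if not keep.any():
            raise UnderdeterminedError("window fully masked by insertion candidates")

        # registration convention: sample[i] lines up with control[i + offset],
        # so control-frame position p reads the sample at p - offset.
        samp_idx = positions - offset
        if samp_idx.min() < 0 or samp_idx.max() >= len(self.sample):
            raise ValueError("sample trace does not cover the decomposition window")
        y = self.sample.channels[samp_idx][keep].ravel()

        # scale sample and control to equal total intensity over the
        # alignment window so weights are comparable mixture fractions.
        w = st.alignment_window
        s0 = max(0, -offset)
        s_tot = self.sample.channels[s0 : s0 + w].sum()
        c_tot = self.control.channels[max(0, offset) : max(0, offset) + w].sum()
        if s_tot <= 0:
            raise ValueError("degenerate sample: zero intensity in alignment window")
        y = y * (c_tot / s_tot)

        X = np.stack([c.profile[keep].ravel() for c in comps], axis=1)
        sizes = np.array([c.indel_size for c in comps])
        if y.size <= X.shape[1]:
            raise UnderdeterminedError(
                f"{y.size} window cells for {X.shape[1]} candidate components"
            )
        return X, y, sizes

    # -- public -------------------------------------------------------------

    def fit(self) -> "TraceDecompositionResults":
        """Register, solve the constrained regression, test components.

        A failed registration does not abort the fit: the sample is
        decomposed at offset 0 and the R^2 < min_r2 rule eliminates the
        well — matching the screening practice of discarding rather than
        erroring on mismatched traces.
        """
        st = self.settings
        try:
            offset = align_control(self.sample, self.control, st)
            registered = True
        except RegistrationError:
            offset, registered = 0, False

        X, y, sizes = self._design(offset)
        if not np.any(y):
            raise ValueError("all-zero sample window: nothing to decompose")

        w, _ = optimize.nnls(X, y)
        fitted = X @ w
        rss = float(np.sum((y - fitted) ** 2))
        # no-intercept regression: uncentered total sum of squares, as in
        # statsmodels OLS without a constant term
        tss = float(y @ y)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0

        # significance: unconstrained OLS on the active set
        active = np.flatnonzero(w > 0)
        pvals = np.ones(len(w))
        bse = np.full(len(w), np.nan)
        if active.size:
            Xa = X[:, active]
            coef, _, rank, _ = np.linalg.lstsq(Xa, y, rcond=None)
            resid = y - Xa @ coef
            dof = y.size - active.size
            sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
            xtx_inv = np.linalg.pinv(Xa.T @ Xa)
            se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
            p = 2.0 * stats.t.sf(np.abs(tstat), df=max(dof, 1))
            p = np.where(np.isfinite(tstat), p, 0.0)
            pvals[active] = p
            bse[active] = se

        total = w.sum()
        freqs = 100.0 * w / total if total > 0 else np.zeros_like(w)

        keep = (w > 0) & (pvals < st.p_cutoff) & (freqs >= st.min_report_freq)
        kept_sizes = sizes[keep]
        kept_w = w[keep]
        if kept_w.sum() > 0:
            kept_freqs = 100.0 * kept_w / kept_w.sum()
        else:
            kept_freqs = np.zeros_like(kept_w)

        variants = pd.DataFrame(
            {
                "indel_size": kept_sizes,
                "frequency": kept_freqs,
                "p_value": pvals[keep],
                "std_err": bse[keep],
            }
        ).sort_values("indel_size", ignore_index=True)

        status = "ok" if r2 >= st.min_r2 else "eliminated_low_fit"
        wt = variants.loc[variants.indel_size == 0, "frequency"]
        efficiency = 100.0 - (float(wt.iloc[0]) if len(wt) else 0.0)
        return TraceDecompositionResults(
            model=self,
            variants=variants,
            r_squared=r2,
            status=status,
            efficiency=efficiency,
            offset=offset,
            registered=registered,
            raw_weights=pd.Series(w, index=sizes),
        )


@dataclass
class TraceDecompositionResults:
    """Estimated indel-allele spectrum of one sample trace.

    ``variants`` holds the retained components (indel_size, frequency in
    percent summing to 100, two-sided p-value and standard error from the
    active-set refit). ``efficiency`` is 100 minus the wild-type frequency.
    ``status`` is ``eliminated_low_fit`` when R^2 < min_r2 and the well
    should be treated as unreadable.
    """

    model: TraceDecomposition
    variants: pd.DataFrame
    r_squared: float
    status: str
    efficiency: float
    offset: int
    registered: bool
    raw_weights: pd.Series

    @property
    def settings(self) -> DecompositionSettings:
        return self.model.settings

    def frequency_table(self) -> pd.Series:
        """Variant frequencies (percent) indexed by indel size."""
        return self.variants.set_index("indel_size")["frequency"]

    def frequency(self, indel_size: int) -> float:
        tbl = self.frequency_table()
        return float(tbl.get(indel_size, 0.0))

    def summary(self) -> str:
        lines = [
            "Trace decomposition results",
            "=" * 46,
            f"components tested   : {len(self.raw_weights)}",
            f"registration offset : {self.offset:+d}"
            + ("" if self.registered else "  (registration failed; offset 0 used)"),
            f"R-squared           : {self.r_squared:.4f}",
            f"status              : {self.status}",
            f"editing efficiency  : {self.efficiency:.1f}%",
            "-" * 46,
        ]
        if len(self.variants):
            lines.append(
                self.variants.to_string(
                    index=False,
                    formatters={
                        "frequency": "{:.2f}".format,
                        "p_value": "{:.2e}".format,
                        "std_err": "{:.3g}".format,
                    },
                )
            )
        else:
            lines.append("(no components retained)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variants": [
                {
                    "indel_size": int(r.indel_size),
                    "frequency": float(r.frequency),
                    "p_value": float(r.p_value),
                }
                for r in self.variants.itertuples()
            ],
            "r_squared": float(self.r_squared),
            "status": self.status,
            "efficiency": float(self.efficiency),
            "offset": int(self.offset),
        }


def decompose(
    sample: Chromatogram,
    control: Chromatogram,
    reference: ReferenceAmplicon,
    settings: DecompositionSettings | None = None,
) -> TraceDecompositionResults:
    """Functional wrapper: ``TraceDecomposition(...).fit()``."""
    return TraceDecomposition(sample, control, reference, settings).fit()


def overall_efficiency(result: TraceDecompositionResults) -> float:
    """Editing efficiency in percent: 100 minus the wild-type frequency.

    Raises
    ------
    ValueError
        If the fit was eliminated (R^2 below threshold) — efficiency from
        an unreliable decomposition is not reported.
    """
    if result.status == "eliminated_low_fit":
        raise ValueError("efficiency unavailable: fit eliminated (low R^2)")
    return result.efficiency


def with_settings(settings: DecompositionSettings, **kwargs) -> DecompositionSettings:
    """Return a copy of ``settings`` with the given fields replaced."""
    return replace(settings, **kwargs)
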