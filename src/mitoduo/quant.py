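"""qPCR quantification and tissue-level mitotype calling.

Standard curves are least-squares fits of Ct against log10(amount);
per-cycle efficiency follows from the slope (E = 10^(-1/slope)). Unknowns
are quantified as amount = amount0 * E^(Ct0 - Ct) with the 1-ng point of
the curve as reference, normalized by the geometric mean of two
housekeeping genes, and tissue mitotype calls are made from the F/M
normalized ratios against a detection limit (default: the amount a Ct-38
well would report).
"""
from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CT_CUTOFF = 38.0
DISCORD_CYCLES = 1.0  # duplicate wells differing by more are flagged


@dataclass
class StandardCurve:
    target: str
    slope: float
    intercept: float  # Ct at 1 ng (log10 amount = 0)
    efficiency: float
    r_squared: float
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(dilutions, target: str = "") -> StandardCurve:
    """Fit Ct vs log10(amount) from (amount, Ct) pairs.

    Requires >= 3 distinct amounts. Efficiencies outside (1, 2.2] and fits
    with r^2 < 0.9 are flagged, not rejected.
    """
    pts = [(float(a), float(c)) for a, c in dilutions]
    if any(a <= 0 for a, _ in pts):
        raise ValueError("standard amounts must be positive")
    if len({a for a, _ in pts}) < 3:
        raise ValueError("standard curve needs >= 3 distinct amounts")
    x = np.log10([a for a, _ in pts])
    y = np.array([c for _, c in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("standard curve slope must be negative (Ct falls with amount)")
    efficiency = 10 ** (-1 / fit.slope)
    flags = []
    if not 1.0 < efficiency <= 2.2:
        flags.append("efficiency_out_of_range")
    r2 = float(fit.rvalue ** 2)
    if r2 < 0.9:
        flags.append("poor_fit")
    return StandardCurve(target, float(fit.slope), float(fit.intercept),
                         float(efficiency), r2, flags)


def quantify(ct: float, curve: StandardCurve,
             reference: tuple[float, float] | None = None) -> float:
    """Template amount (ng) from a Ct: amount0 * E^(Ct0 - ct).

    The default reference is the curve's 1-ng point (Ct0 = intercept,
    amount0 = 1), which is equivalent to reading the amount off the curve.
    """
    if curve.efficiency <= 1.0:
        raise ValueError("degenerate curve: efficiency must be > 1")
    ct0, amount0 = reference if reference is not None else (curve.intercept, 1.0)
    return amount0 * curve.efficiency ** (ct0 - ct)


def detection_limit(curve: StandardCurve,
                    ct_cutoff: float = DEFAULT_CT_CUTOFF) -> float:
    """Amount corresponding to the Ct cutoff (default 38 cycles)."""
    return quantify(ct_cutoff, curve)


def normalize(target_ng: float, hk1_ng: float, hk2_ng: float) -> float:
    """Target over the geometric mean of the two housekeeping amounts."""
    if hk1_ng <= 0 or hk2_ng <= 0:
        raise ValueError("housekeeping amounts must be > 0")
    return target_ng / math.sqrt(hk1_ng * hk2_ng)


_BUCKETS = ("<1", "1-2", ">2")


@dataclass
class TissueMitotypeCall:
    sample: str
    tissue: str
    ratio_F: float
    ratio_M: float
    call: str  # homoplasmic_F, homoplasmic_M, heteroplasmic, FAIL
    log10_imbalance: float = float("nan")
    imbalance_bucket: str = ""


def call_tissue_mitotype(ratio_f: float, ratio_m: float, detection_limit: float,
                         sample: str = "", tissue: str = "") -> TissueMitotypeCall:
    """Classify a tissue from its F/M normalized abundances.

    Homoplasmic when the minor type is below the detection limit;
    heteroplasmic otherwise, with the major/minor imbalance bucketed in
    orders of magnitude (<1, 1-2, >2); FAIL when both are undetected.
    """
    if ratio_f < 0 or ratio_m < 0:
        raise ValueError("ratios must be >= 0")
    f_det = ratio_f >= detection_limit
    m_det = ratio_m >= detection_limit
    if not f_det and not m_det:
        return TissueMitotypeCall(sample, tissue, ratio_f, ratio_m, "FAIL")
    if f_det and m_det:
        major, minor = max(ratio_f, ratio_m), min(ratio_f, ratio_m)
        imb = math.log10(major / minor) if minor > 0 else float("inf")
        bucket = _BUCKETS[0] if imb < 1 else (_BUCKETS[1] if imb <= 2 else _BUCKETS[2])
        return TissueMitotypeCall(sample, tissue, ratio_f, ratio_m,
                                  "heteroplasmic", imb, bucket)
    call = "homoplasmic_F" if f_det else "homoplasmic_M"
    return TissueMitotypeCall(sample, tissue, ratio_f, ratio_m, call)


CopyNumberFold = namedtuple("CopyNumberFold", ["fold", "ci_low", "ci_high"])


def copy_number_fold(group_a, group_b, bootstrap_reps: int = 1000,
                     seed: int | None = None, ci: float = 0.95) -> CopyNumberFold:
    """Ratio of group medians with a percentile bootstrap CI.

    Used for the mtDNA copy-number contrast (normalized cytb abundance in
    M-carriers over F-carriers).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 individuals per group")
    if np.median(b) <= 0 or np.median(a) <= 0:
        raise ValueError("degenerate group: non-positive median")
    fold = float(np.median(a) / np.median(b))
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        ra = rng.choice(a, len(a))
        rb = rng.choice(b, len(b))
        mb = np.median(rb)
        reps[r] = np.median(ra) / mb if mb > 0 else np.nan
    alpha = (1 - ci) / 2
    lo, hi = np.nanquantile(reps, [alpha, 1 - alpha])
    return CopyNumberFold(fold, float(lo), float(hi))


# ---------------------------------------------------------------------------
# Plate processing
# ---------------------------------------------------------------------------

def process_plate(plate: pd.DataFrame,
                  targets: tuple[str, str] = ("cytbF", "cytbM"),
                  housekeeping: tuple[str, str] = ("18S", "28S"),
                  ct_cutoff: float = DEFAULT_CT_CUTOFF,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, StandardCurve]]:
    """Full plate pipeline: curves, amounts, normalization, mitotype calls.

    ``plate`` is the long-format table written by the simulator (columns
    role, sample, tissue, target, known_amount_ng, replicate, ct).
    Duplicate wells are averaged on the Ct scale; pairs discordant by more
    than one cycle are flagged, not dropped; all-NaN wells (no
    amplification) quantify as zero with a below_detection flag.

    The housekeeping pair is a configuration input; a stability-based
    selection criterion could slot in where the pair is chosen.
    """
    needed = {"role", "sample", "tissue", "target", "known_amount_ng", "replicate", "ct"}
    if not needed <= set(plate.columns):
        raise ValueError(f"plate table needs columns {sorted(needed)}")
    curves: dict[str, StandardCurve] = {}
    std = plate[plate.role == "standard"]
    for target, grp in std.groupby("target"):
        curves[target] = fit_standard_curve(
            list(zip(grp.known_amount_ng, grp.ct)), target=str(target))
    for t in (*targets, *housekeeping):
        if t not in curves:
            raise ValueError(f"no standard curve wells for target {t}")

    unk = plate[plate.role == "unknown"]
    rows = []
    for (sample, tissue, target), grp in unk.groupby(["sample", "tissue", "target"]):
        cts = grp.ct.to_numpy(dtype=float)
        flags = []
        finite = cts[np.isfinite(cts)]
        if finite.size == 0:
            amount, mean_ct = 0.0, float("nan")
            flags.append("below_detection")
        else:
            if finite.size >= 2 and (finite.max() - finite.min()) > DISCORD_CYCLES:
                flags.append("replicate_discord")
            mean_ct = float(finite.mean())
            amount = quantify(mean_ct, curves[target])
            if mean_ct > ct_cutoff:
                flags.append("below_detection")
                amount = 0.0
        rows.append((sample, tissue, target, mean_ct, amount, ";".join(flags)))
    amounts = pd.DataFrame(rows, columns=["sample", "tissue", "target",
                                          "mean_ct", "amount_ng", "flags"])

    call_rows = []
    quant_rows = []
    for (sample, tissue), grp in amounts.groupby(["sample", "tissue"]):
        by_target = grp.set_index("target")
        try:
            hk1 = float(by_target.loc[housekeeping[0], "amount_ng"])
            hk2 = float(by_target.loc[housekeeping[1], "amount_ng"])
        except KeyError as e:
            raise ValueError(f"sample {sample}/{tissue} lacks housekeeping target {e}")
        geo = math.sqrt(hk1 * hk2) if hk1 > 0 and hk2 > 0 else float("nan")
        norm = {}
        for t in targets:
            amt = float(by_target.loc[t, "amount_ng"]) if t in by_target.index else 0.0
            norm[t] = amt / geo if geo and not math.isnan(geo) else float("nan")
            quant_rows.append((sample, tissue, t, amt, norm[t],
                               str(by_target.loc[t, "flags"]) if t in by_target.index else ""))
        det = min(detection_limit(curves[t], ct_cutoff) for t in targets)
        det_norm = det / geo if geo and not math.isnan(geo) else float("inf")
        c = call_tissue_mitotype(norm[targets[0]], norm[targets[1]], det_norm,
                                 sample=str(sample), tissue=str(tissue))
        call_rows.append((c.sample, c.tissue, c.ratio_F, c.ratio_M, c.call,
                          c.log10_imbalance, c.imbalance_bucket))
    quant_df = pd.DataFrame(quant_rows, columns=["sample", "tissue", "target",
                                                 "amount_ng", "normalized", "flags"])
    calls_df = pd.DataFrame(call_rows, columns=["sample", "tissue", "ratio_F",
                                                "ratio_M", "call",
                                                "log10_imbalance", "imbalance_bucket"])
    return quant_df, calls_df, curves
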