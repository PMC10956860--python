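"""Published benchmark values consumed by the comparison and grading machinery.

Two small reference tables accompany the method's published evaluation on
photographic tapping-panel images.  The images themselves are not
redistributable, but the printed numbers are inputs to the rank-aggregation,
signed-rank and grading machinery, so they ship here as literal data.

``benchmark_metrics()`` — per (image group, optimizer) scar/latex thresholds,
runtime and the PSNR / FSIM / SSIM of the reconstructed segmentation, for
seven optimizer-driven multi-threshold segmenters on four image groups.

``severity_reference()`` — latex and tapping-cut pixel counts with the
resulting area ratio and severity grade for fifteen graded panel images.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["benchmark_metrics", "severity_reference", "ALGORITHMS", "REFERENCE_ALGORITHM"]

ALGORITHMS = ("SSA", "WOA", "WSO", "GWO", "AHA", "CSA", "DBO")
REFERENCE_ALGORITHM = "DBO"

_METRIC_ROWS = [
    # group, algorithm, scar_threshold, latex_threshold, time_s, psnr, fsim, ssim
    ("4-6", "SSA", 170.607846, 202.3673229, 0.454, 8.149481674, 0.514599926, 0.126894101),
    ("4-6", "WOA", 193.3105468, 255.4191533, 0.292, 7.569149399, 0.505307484, 0.114336442),
    ("4-6", "WSO", 174.129266, 202.9681429, 0.293, 8.067329821, 0.513251516, 0.123459772),
    ("4-6", "GWO", 170.9923696, 202.4617205, 0.297, 8.149481674, 0.514599926, 0.126894101),
    ("4-6", "AHA", 170.6434785, 202.960859, 0.326, 8.149481674, 0.514599926, 0.126894101),
    ("4-6", "CSA", 170.704867, 202.3591813, 0.293, 8.149481674, 0.514599926, 0.126894101),
    ("4-6", "DBO", 171.4228188, 204.8375643, 0.372, 8.165899285, 0.521412398, 0.127876046),
    ("4-12", "SSA", 155.5854386, 207.8677594, 0.44, 8.289015524, 0.557163498, 0.09489891),
    ("4-12", "WOA", 149.0694241, 203.5416501, 0.293, 15.17593885, 0.590534328, 0.550520428),
    ("4-12", "WSO", 154.2989164, 202.5409691, 0.283, 8.333545453, 0.558486259, 0.100172884),
    ("4-12", "GWO", 157.7155776, 205.8915754, 0.3, 8.224993212, 0.556169337, 0.093358665),
    ("4-12", "AHA", 155.2227337, 207.6226922, 0.332, 8.289015524, 0.557163498, 0.09489891),
    ("4-12", "CSA", 155.304461, 207.5493689, 0.297, 8.289015524, 0.557163498, 0.09489891),
    ("4-12", "DBO", 152.3887825, 204.0333982, 0.335, 8.364000908, 0.557133382, 0.100182992),
    ("4-19", "SSA", 171.4507, 193.7683, 0.45, 11.44445, 0.444172, 0.074768),
    ("4-19", "WOA", 171.3533, 193.0518, 0.357, 11.37516, 0.432095, 0.071192),
    ("4-19", "WSO", 166.0914, 195.5994, 0.338, 11.49231, 0.440329, 0.076701),
    ("4-19", "GWO", 171.3085, 193.8558, 0.931, 11.44445, 0.444172, 0.074768),
    ("4-19", "AHA", 171.8939, 193.1976, 0.596, 11.44445, 0.444172, 0.074768),
    ("4-19", "CSA", 168.8158, 193.9061, 0.366, 11.51899, 0.452194, 0.078359),
    ("4-19", "DBO", 166.6904, 193.8078, 0.462, 11.54439, 0.452779, 0.079371),
    ("4-20", "SSA", 197.4308, 209.5352, 0.601, 6.124981, 0.60167, 0.041313),
    ("4-20", "WOA", 182.7351, 208.6473, 0.4, 11.72238, 0.613376, 0.562652),
    ("4-20", "WSO", 193.5352, 213.5405, 0.871, 6.128787, 0.606108, 0.045566),
    ("4-20", "GWO", 197.0394, 209.767, 0.491, 6.124981, 0.60167, 0.041313),
    ("4-20", "AHA", 197.4107, 209.7839, 0.405, 6.124981, 0.60167, 0.041313),
    ("4-20", "CSA", 197.0325, 209.6747, 0.361, 6.124981, 0.60167, 0.041313),
    ("4-20", "DBO", 181.2085, 208.6152, 0.464, 7.256473, 0.641461, 0.133997),
]

_SEVERITY_ROWS = [
    # level, image, latex_px, scar_px, ratio, grade
    (1, 13, 7681, 11099, 0.692044328, 1),
    (1, 14, 13842, 24797, 0.558212687, 1),
    (1, 15, 11545, 18598, 0.620765674, 1),
    (2, 4, 41651, 96132, 0.433268839, 2),
    (2, 10, 182369, 492541, 0.370261562, 2),
    (2, 26, 263777, 612148, 0.430903964, 2),
    (3, 10, 175705, 547090, 0.32116288, 3),
    (3, 11, 173405, 590372, 0.293721586, 3),
    (3, 12, 147825, 505293, 0.292553034, 3),
    (4, 11, 15753, 194899, 0.080826479, 5),
    (4, 12, 60878, 525198, 0.115914379, 4),
    (4, 16, 19962, 193855, 0.102973872, 4),
    (5, 16, 126, 12723, 0.009903325, 5),
    (5, 17, 128, 11821, 0.010828187, 5),
    (5, 18, 189, 399566, 0.000473013, 5),
]


def benchmark_metrics() -> pd.DataFrame:
    """Long-form table: group, algorithm, thresholds, runtime, psnr, fsim, ssim."""
    return pd.DataFrame(
        _METRIC_ROWS,
        columns=[
            "group",
            "algorithm",
            "scar_threshold",
            "latex_threshold",
            "time_s",
            "psnr",
            "fsim",
            "ssim",
        ],
    )


def severity_reference() -> pd.DataFrame:
    """Graded panel images: level, image, latex_px, scar_px, ratio, grade."""
    return pd.DataFrame(
        _SEVERITY_ROWS,
        columns=["level", "image", "latex_px", "scar_px", "ratio", "grade"],
    )
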