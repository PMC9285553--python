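"""Simulate and analyse a small multicentre test-retest study.

Four sites (two PGSE + one SE + one STEAM arm) at realistic SNR, with a 2%
inter-site MD scatter and two scans per arm.  Runs the full central
analysis and prints the report: MD/FA tables, accuracy, precision,
grouped CVs, Bland-Altman repeatability.
"""

from dtiphantom import analyse_study, default_layout, render_report, simulate_study
from dtiphantom.phantom import NoiseModel, SiteAcquisition, SiteEffect

layout = default_layout(grid_shape=(48, 48, 1))
sites = [
    SiteAcquisition("A", "PGSE", 0.0, 10, NoiseModel("rician", 23.3), SiteEffect(0.010)),
    SiteAcquisition("B", "PGSE", 0.0, 10, NoiseModel("rician", 23.3), SiteEffect(-0.015)),
    SiteAcquisition("A", "SE", 5.0, 10, NoiseModel("rician", 19.9), SiteEffect(0.010)),
    SiteAcquisition("B", "STEAM", 39.0, 10, NoiseModel("rician", 20.8), SiteEffect(-0.015)),
]
study = simulate_study(layout, sites, seed=42)
analysis = analyse_study(study, bootstrap_n=500, seed=42)
print(render_report(analysis))
# The intersite CV section reflects the injected +/-1.0-1.5% site biases;
# the Bland-Altman mean differences sit near zero because no systematic
# scan-2 shift was injected.
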