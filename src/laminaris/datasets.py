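"""Small reference datasets bundled with the package.

``PAIRED_SPIKE_NEUROPHONIC_SITES`` lists ten published measurements where a
spike recording and a neurophonic recording were obtained with the same
electrode at (nearly) the same position in the nucleus. Each row gives the
electrode-position difference, the ITD-test frequency and best ITD of each
member of the pair. They serve as inputs for the paired-mismatch
computation, which quantifies how faithfully the field potential mirrors
nearby spiking activity.
"""

from __future__ import annotations

import pandas as pd

#: columns: distance_um, spike_frequency (Hz), spike_best_itd (μs),
#: neuro_frequency (Hz), neuro_best_itd (μs), single_unit (bool)
PAIRED_SPIKE_NEUROPHONIC_SITES = (
    dict(distance_um=0,  spike_frequency=400.0,  spike_best_itd=-179.0,
         neuro_frequency=400.0,  neuro_best_itd=-250.0, single_unit=True),
    dict(distance_um=0,  spike_frequency=500.0,  spike_best_itd=-500.0,
         neuro_frequency=500.0,  neuro_best_itd=-400.0, single_unit=False),
    dict(distance_um=0,  spike_frequency=571.0,  spike_best_itd=-612.0,
         neuro_frequency=571.0,  neuro_best_itd=-700.0, single_unit=True),
    dict(distance_um=0,  spike_frequency=714.0,  spike_best_itd=-472.0,
         neuro_frequency=800.0,  neuro_best_itd=-375.0, single_unit=True),
    dict(distance_um=0,  spike_frequency=800.0,  spike_best_itd=625.0,
         neuro_frequency=800.0,  neuro_best_itd=625.0,  single_unit=True),
    dict(distance_um=15, spike_frequency=800.0,  spike_best_itd=-280.0,
         neuro_frequency=800.0,  neuro_best_itd=-250.0, single_unit=True),
    dict(distance_um=0,  spike_frequency=1000.0, spike_best_itd=-480.0,
         neuro_frequency=1000.0, neuro_best_itd=-400.0, single_unit=False),
    dict(distance_um=0,  spike_frequency=1111.0, spike_best_itd=420.0,
         neuro_frequency=1111.0, neuro_best_itd=410.0,  single_unit=True),
    dict(distance_um=0,  spike_frequency=1250.0, spike_best_itd=-64.0,
         neuro_frequency=1250.0, neuro_best_itd=0.0,    single_unit=False),
    dict(distance_um=0,  spike_frequency=1316.0, spike_best_itd=-252.0,
         neuro_frequency=1316.0, neuro_best_itd=-304.0, single_unit=False),
)


def paired_sites_table() -> pd.DataFrame:
    """The paired spike/neurophonic measurements as a DataFrame."""
    return pd.DataFrame(PAIRED_SPIKE_NEUROPHONIC_SITES)


def paired_mismatch_table() -> pd.DataFrame:
    """Per-pair best-ITD (μs) and best-IPD (cycles) mismatches."""
    from .delay import paired_mismatch

    df = paired_sites_table()
    diffs = [paired_mismatch((r.spike_frequency, r.spike_best_itd),
                             (r.neuro_frequency, r.neuro_best_itd))
             for r in df.itertuples()]
    df = df.copy()
    df["itd_mismatch_us"] = [d[0] for d in diffs]
    df["ipd_mismatch_cycles"] = [d[1] for d in diffs]
    df["frequency_mismatch_hz"] = (df.spike_frequency - df.neuro_frequency).abs()
    return df
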