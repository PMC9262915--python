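import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from hippoquant import behavior, photometry, swr, synth

hypothesis_settings.register_profile("no_db", database=None)
hypothesis_settings.load_profile("no_db")


@pytest.fixture(scope="session")
def lfp_session():
    """600 s synthetic LFP at 2 kHz with 0.3 Hz ripples at 6 SD, plus the
    detection chain run on it (envelope, immobility baseline, events)."""
    cfg = synth.LfpSimConfig(duration_s=600.0, rate_hz=2000.0,
                             ripple_rate_hz=0.3, ripple_amp_sd=6.0, seed=1)
    sig, truth, mobility = synth.simulate_lfp(cfg)
    immobility = mobility.complement((0.0, cfg.duration_s))
    env = swr.ripple_envelope(sig)
    stats = swr.baseline_stats(env, immobility)
    events = swr.detect_swr(env, stats)
    return {"cfg": cfg, "signal": sig, "truth": truth, "mobility": mobility,
            "immobility": immobility, "envelope": env, "stats": stats,
            "events": events}


@pytest.fixture(scope="session")
def ipsc_session():
    """120 s voltage-clamp trace at the hardware rate with a 5 Hz / 50 pA
    event train in 5 pA noise, and the detector output."""
    from hippoquant import ipsc
    cfg = synth.IpscSimConfig(seed=1)
    sig, truth = synth.simulate_ipsc_trace(cfg)
    events = ipsc.detect_ipsc_events(sig)
    return {"cfg": cfg, "signal": sig, "truth": truth, "events": events}


@pytest.fixture(scope="session")
def photometry_session():
    """300 s photometry session with locomotion coupling, processed end to end."""
    cfg = synth.PhotometrySimConfig(seed=5)
    f465, f405, track, truth = synth.simulate_photometry(cfg)
    dff = photometry.isosbestic_dff(f465, f405)
    behavior.kinematics(track)
    return {"cfg": cfg, "f465": f465, "f405": f405, "track": track,
            "truth": truth, "dff": dff}


@pytest.fixture(scope="session")
def stain_image():
    img, truth = synth.simulate_stain_image(synth.StainSimConfig(seed=0))
    return img, truth


def interval_jaccard(a, b, span, n_grid=20001):
    """Jaccard overlap of two interval sets evaluated on a fine time grid."""
    grid = np.linspace(span[0], span[1], n_grid)
    ma, mb = a.contains(grid), b.contains(grid)
    union = int(np.count_nonzero(ma | mb))
    return int(np.count_nonzero(ma & mb)) / union if union else 1.0
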