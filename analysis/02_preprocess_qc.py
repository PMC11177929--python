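"""Quality control of the simulated memory session.

Applies modified-z artifact-trial rejection to the pooled delay-rate
distribution and the evoked-response SNR criterion per channel, and writes
a QC summary to results/qc.json. On clean synthetic data both filters
should pass nearly everything; the point is to exercise the thresholds the
recorded data would face.
"""

import json
from pathlib import Path

import numpy as np

from wmv1.cmi import epoch_rates
from wmv1.pipeline_io import read_session
from wmv1.preprocess import channel_snr, reject_artifact_trials

SESSION = Path("results/sessions/memory.h5")


def main() -> None:
    s = read_session(SESSION)
    rates = epoch_rates(s, (700.0, 1700.0))
    keep = reject_artifact_trials(rates.mean(axis=1))
    times = np.arange(-150.0, 200.0)
    snrs = {}
    for e in s.electrodes:
        psth = s.binned((-150.0, 200.0), e).mean(axis=0) * 1000.0
        snr, retained = channel_snr(psth, times)
        snrs[int(e)] = {"snr": round(float(snr), 2), "retained": bool(retained)}
    report = {
        "n_trials": int(s.n_trials),
        "trials_rejected": int((~keep).sum()),
        "channels": snrs,
        "channels_retained": sum(v["retained"] for v in snrs.values()),
    }
    Path("results/qc.json").write_text(json.dumps(report, indent=2))
    print(f"rejected {report['trials_rejected']}/{report['n_trials']} trials; "
          f"retained {report['channels_retained']}/{len(snrs)} channels")


if __name__ == "__main__":
    main()
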