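#!/usr/bin/env python
"""Run-by-run CSP spatial-filter stability within a closed-loop session.

Batch retraining refits the CSP filters after every run, so the electrode
weighting drifts run by run even on stationary data — the instability that
motivates comparing data-driven spatial filtering against the fixed
Laplacian.  Tracks the top filter's coefficient at the hand-area electrodes
across runs and its dispersion; also shows dispersion shrinking when more
trials feed each refit.  Writes weight_trace_<ch>.tsv and
weight_dispersion.tsv under results/.
"""

from pathlib import Path

from mibci.closed_loop import run_session
from mibci.decoders import CSPModel, class_covariance, fit_csp
from mibci.montage import standard_layout
from mibci.offline_eval import weight_variation, write_weight_trace
from mibci.preproc import epoch
from mibci.synthgen import SynthConfig, generate_session

OUT = Path("results")
OUT.mkdir(exist_ok=True)

layout = standard_layout(64)
res = run_session(SynthConfig(erd_depth=0.6, snr=2.0, seed=9200), layout, "CSP/S")
models = [CSPModel.from_dict(s["csp"]) for s in res.snapshots if s.get("csp")]
print(f"session PVC {res.session_pvc:.3f}; {len(models)} per-run CSP models")

rows = []
for ch in ("C3", "C4", "Cz"):
    tr = weight_variation(models, ch)
    write_weight_trace(tr, OUT / f"weight_trace_{ch}.tsv")
    rows.append((ch, len(models), tr.dispersion))
    print(f"  {ch}: run-to-run coefficient dispersion {tr.dispersion:.4f}")

# dispersion vs trials-per-refit on stationary data
cfg = SynthConfig(erd_depth=0.6, snr=2.0, n_runs=8, seed=9201)
sub = layout.subset(["C3", "C4", "Cz", "F3", "F4", "T7", "T8", "P3", "P4"])
rec, sch = generate_session(cfg, sub)
eps = epoch(rec, sch)
for per_model in (25, 50, 100):
    models = []
    for start in range(0, 200, per_model):
        pool = eps[start:start + per_model]
        cl = class_covariance([e for e in pool if e.label == "left"])
        cr = class_covariance([e for e in pool if e.label == "right"])
        models.append(fit_csp(cl, cr, 3, eps[0].channel_names))
    d = weight_variation(models, "C3").dispersion
    rows.append((f"C3@{per_model}", len(models), d))
    print(f"  C3, {per_model} trials/refit: dispersion {d:.4f}")

with open(OUT / "weight_dispersion.tsv", "w") as fh:
    fh.write("electrode\tn_models\tdispersion\n")
    for ch, n, d in rows:
        fh.write(f"{ch}\t{n}\t{d:.5f}\n")
print(f"wrote {OUT / 'weight_dispersion.tsv'}")
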