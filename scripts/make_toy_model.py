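"""Regenerate the bundled 27-letter toy structural-alphabet model.

Fits a 27-state Gaussian HMM by Baum-Welch on descriptor sequences from a
fixed-seed collection of synthetic motifs (helices, strands, hairpins,
coil) and writes src/safrag/data/sa27_toy_model.json.  The result is a
synthetic stand-in alphabet for testing and demonstration, not a published
parameter set.

Run from the repository root:  python scripts/make_toy_model.py
"""

import json
from pathlib import Path

import numpy as np

from safrag import fit_baum_welch
from safrag.synthetic import build_chain

SEED = 20240101
OUT = Path(__file__).resolve().parents[1] / "src" / "safrag" / "data" / "sa27_toy_model.json"


def training_traces():
    """Assembled multi-motif chains, so the alphabet also sees motif
    junctions and heterogeneous coil, not just isolated ideal motifs."""
    rng = np.random.default_rng(SEED)
    return [
        build_chain(
            int(rng.integers(40, 80)),
            composition=(0.35, 0.2, 0.15, 0.3),
            noise_sd=0.25,
            rng=rng,
            chain_id=f"train{i}",
        )
        for i in range(80)
    ]


def main() -> None:
    traces = training_traces()
    model = fit_baum_welch(
        traces, n_states=27, seed=SEED % (2**31), max_iter=60, tol=1e-3,
        transition_stickiness=20.0, covariance_floor=1e-3, covariance_cap=0.5,
    )
    d = model.to_dict()
    # compact but reproducible serialization
    def r(x, nd=8):
        if isinstance(x, list):
            return [r(v, nd) for v in x]
        return round(x, nd) if isinstance(x, float) else x

    payload = {k: (r(v) if k != "labels" else v) for k, v in d.items()}
    # rounding can leave rows summing to 1 +- 1e-8; renormalize exactly
    t = np.array(payload["transitions"])
    payload["transitions"] = (t / t.sum(axis=1, keepdims=True)).tolist()
    p = np.array(payload["initial"])
    payload["initial"] = (p / p.sum()).tolist()
    OUT.write_text(json.dumps(payload))
    print(f"wrote {OUT} ({OUT.stat().st_size / 1024:.1f} KiB, "
          f"{len(model.log_likelihoods)} EM iterations)")


if __name__ == "__main__":
    main()
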