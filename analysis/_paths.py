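"""Shared locations for the analysis drivers (relative to the repo root)."""
import os

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
SCRATCH = os.path.join(ROOT, "scratch", "analysis")
os.makedirs(RESULTS, exist_ok=True)
os.makedirs(SCRATCH, exist_ok=True)
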