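#!/usr/bin/env python
"""Generate a cohort of synthetic new/old task sessions and export to NWB.

Builds six sessions across the three task variants and recording sites
(C/H/T subject prefixes) with the default behavior (d' = 1.5) and unit
composition (20% visually selective, 10% memory selective, 5 Hz baseline),
then writes one NWB-style file per session.  Session files are HDF5 and go
under scratch/nwb/; downstream drivers read only those files.
"""

from pathlib import Path

from newold.cli import generate_sessions_to_nwb
from newold.synthetic_session import GeneratorConfig

ROOT = Path(__file__).resolve().parents[1]
NWB_DIR = ROOT / "scratch" / "nwb"

CONFIGS = [
    GeneratorConfig(session_id=f"{sub}_s{k}", subject_id=sub, variant=variant,
                    seed=seed)
    for seed, (sub, variant, k) in enumerate(
        [("C01", 1, 1), ("C01", 2, 2), ("H03", 1, 1),
         ("H04", 3, 1), ("T02", 2, 1), ("T05", 3, 1)]
    )
]


def main() -> None:
    paths = generate_sessions_to_nwb(CONFIGS, NWB_DIR)
    print(f"wrote {len(paths)} session files to {NWB_DIR}:")
    for p in paths:
        print(f"  {p.name}")


if __name__ == "__main__":
    main()
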