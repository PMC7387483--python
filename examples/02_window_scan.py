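"""Sliding-window detection of a cationic amphipathic helix.

Builds a toy mature sequence with an amphipathic KLAK-style core flanked by
neutral polar sequence, scans 18-residue windows against the cationic
threshold box, and prints the passing windows and the merged segment.
"""

from lcampscreen import CATIONIC_BOX, merge_windows, scan_windows

mature = "SNQTSNQTSN" + "KLAKSLAKKLLSQAANKA" + "TSNQTSNQTSNQ"
windows = scan_windows(mature, CATIONIC_BOX, parent_id="toy")

print(f"{len(windows)} passing window(s):")
for w in windows:
    print(f"  [{w.start:2d},{w.end:2d}) {w.seq}  H={w.profile.H:+.3f} "
          f"muH={w.profile.muH:.3f} z={w.profile.z:+d}")

for seg in merge_windows(windows):
    print(f"merged segment [{seg.start},{seg.end}), best window starts at "
          f"{seg.best_window.start} (muH={seg.best_window.profile.muH:.3f})")

# Only windows overlapping the planted amphipathic core satisfy all bounds
# (H in [0,0.6], muH in [0.1,1.0], z in [3,10] plus composition rules);
# overlapping passes merge into one candidate segment.
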