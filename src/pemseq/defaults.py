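"""Shared pipeline defaults.

All thresholds are configurable at call sites; these constants are the
documented defaults and are echoed into run-report metadata.
"""

#: indel vs large-deletion boundary (bp); deletions <= D_LARGE count as indels
D_LARGE = 200

#: insertions up to this length with no vector match are counted as indels
MAX_INSERTION_INDEL = 50

#: half-width (bp) of the window around an off-target cut site within which a
#: translocation junction is attributed to that off-target
OFFTARGET_WINDOW = 100

#: exact-match seed length for the local aligner
SEED_LEN = 20

#: minimum local-alignment score to report a hit
MIN_SCORE = 30

#: minimum prey length (nt) required to attempt mapping a junction partner
MIN_PREY_LEN = 20

#: minimum colinear nt past the cut site for an uncut call
UNCUT_MIN_COLINEAR = 10

#: tolerance (bp) for "junction at the presumable cut site" checks
CUT_SITE_TOL = 3

#: fixed 6-nt spacer between the UMI and the bait in the digital read layout
READ_SPACER = "ACGCGT"

#: UMI length (nt)
UMI_LEN = 12

#: maximum read length (nt) emitted by the simulator
READ_LEN = 250

#: local-alignment scoring
MATCH = 1
MISMATCH = -4
GAP_OPEN = -6
GAP_EXTEND = -1

#: hotspot binning
HOTSPOT_BIN = 100
HOTSPOT_MIN_SUPPORT = 3

#: joint spacer+PAM mismatch bound for off-target candidacy
MAX_GUIDE_MM = 8
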