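"""Validate a taxa reference list and print the issue report.

The list below contains three deliberate defects: a conflicting duplicate
(the same taxon assigned to both ecological groups — an error, since the
index would be ambiguous), a benign duplicate (warning; the first record
wins), and an unrecognized ecological-group code.
"""

import io
import sys

from microgambi import parse_taxa_list, summarize_reference
from microgambi.taxa import write_issue_report

TAXA_LIST = """\
n\ttaxon\tncbi\tworms\tEG
1\tDesulfobacter\t\t\tI
2\tVibrio\t\t\tIII
3\tVibrio sp.\t\t\tI
4\tdesulfobacter\t\t\tI
5\tStrangebacter\t\t\tEG VII
"""

ref = parse_taxa_list(io.StringIO(TAXA_LIST))

write_issue_report(ref.issues, sys.stdout)
s = summarize_reference(ref)
print(f"\nretained {s.total} records "
      f"({s.n_egi} EGI, {s.n_egiii} EGIII, {s.n_not_assigned} not assigned)")

# Error-level issues (CONFLICTING_EG, INVALID_EG_CODE) drop the offending
# row; warnings keep the first occurrence.  In strict parsing mode any
# error aborts instead.
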