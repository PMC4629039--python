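"""Score a pair of protein sequences three ways.

The reference Gotoh recurrence, the row-staged two-pass variant, and
(for short inputs) the exhaustive enumeration oracle must all report
the same optimal local alignment score.
"""

from fdsw import (
    AlignmentParams,
    load_substitution_matrix,
    sw_score,
    sw_score_bruteforce,
    sw_score_row_staged,
)

matrix = load_substitution_matrix("BLOSUM62")
params = AlignmentParams(gap_open=10, gap_extend=2)

s1, s2 = "WWAWW", "WWWW"
print(f"query   : {s1}")
print(f"subject : {s2}")
print(f"reference DP      : {sw_score(s1, s2, matrix, params)}")
print(f"row-staged DP     : {sw_score_row_staged(s1, s2, matrix, params)}")
print(f"enumeration oracle: {sw_score_bruteforce(s1, s2, matrix, params)}")
print()
print("All three agree: the optimum aligns the four tryptophans "
      "(4 x 11 = 44) and deletes the interior alanine with one "
      "length-1 gap (10 + 2), giving 32. The score is the similarity "
      "of the best local match, not a full-length alignment.")
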