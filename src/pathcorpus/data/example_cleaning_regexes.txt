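# Example line-removal patterns: clinic headers, fax banners, page footers,
# accession banners and similar site-identifying boilerplate. Search
# semantics, case-insensitive by default. Supply your own list for real
# report sets.
PAGE \d+ OF \d+
^PAGE:?\s*\d+$
FAX[:#]?\s*\(?\d{3}\)?[-. ]?\d{3}[-. ]?\d{4}
TEL(EPHONE)?[:#]?\s*\(?\d{3}\)?[-. ]?\d{3}[-. ]?\d{4}
^ACCESSION\s*(#|NO\.?|NUMBER)
^SPECIMEN\s*#\s*:?\s*$
DEPARTMENT OF PATHOLOGY AND LABORATORY MEDICINE
^SURGICAL PATHOLOGY REPORT$
^FINAL REPORT$
^\s*CONTINUED ON NEXT PAGE
^PRINTED BY\b
^PRINTED ON:?\s
^ELECTRONICALLY SIGNED
^REPORT ELECTRONICALLY SIGNED OUT
^MEDICAL RECORD (#|NO\.?)
^MRN[:#]
^D\.?O\.?B\.?[:#]
^DATE OF BIRTH
^COLLECTED:?\s+\d
^RECEIVED:?\s+\d
^CC[:#]\s
^\*{3,}\s*END OF REPORT
AMENDED REPORT HEADER
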