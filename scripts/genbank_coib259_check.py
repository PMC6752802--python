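"""Online integration check: the 13 Spodoptera COIB GenBank records
share a 259-bp segment.

Fetches the accessions behind the COIB259 reference panel from NCBI
(requires network access; not part of the offline test suite), trims
them to their common overlap by pairwise anchoring against the fall
armyworm record, and reports the shared segment length, which should
be 259 bp.

Usage:
    python scripts/genbank_coib259_check.py [--email you@example.org]
"""

import argparse
import sys
import urllib.parse
import urllib.request

ACCESSIONS = [
    "HQ177287", "HQ177295", "HQ177306", "HQ177313", "HQ177321",
    "HQ177334", "HQ177339", "HQ177354", "HQ177364", "HQ177382",
    "HQ177392", "HQ177407", "HQ177375",
]

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_fasta(accessions, email):
    params = urllib.parse.urlencode(
        {
            "db": "nuccore",
            "id": ",".join(accessions),
            "rettype": "fasta",
            "retmode": "text",
            "email": email,
        }
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        return resp.read().decode()


def parse_fasta(text):
    records, name, chunks = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip().upper())
    if name:
        records.append((name, "".join(chunks)))
    return records


def shared_segment_length(seqs):
    """Length of the longest window of the shortest sequence found
    (at >=80% identity) in every other sequence."""
    from fawkit.markers import locate_segment

    anchor = min(seqs, key=len)
    lo_best = 0
    hi_best = len(anchor)
    # trim the anchor until every sequence contains it
    lo, hi = 0, len(anchor)
    while hi - lo > 0:
        window = anchor[lo:hi]
        if all(
            locate_segment(s, anchor, (lo, hi)).ok
            for s in seqs
            if len(s) >= hi - lo
        ):
            return hi - lo
        lo += 1
        hi -= 1
    return 0


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="")
    args = parser.parse_args()
    try:
        text = fetch_fasta(ACCESSIONS, args.email)
    except OSError as exc:
        sys.exit(f"network fetch failed ({exc}); this check needs internet access")
    records = parse_fasta(text)
    if len(records) != len(ACCESSIONS):
        sys.exit(f"expected {len(ACCESSIONS)} records, got {len(records)}")
    length = shared_segment_length([s for _, s in records])
    print(f"shared segment length across {len(records)} records: {length} bp")
    print("expected: 259 bp")


if __name__ == "__main__":
    main()
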