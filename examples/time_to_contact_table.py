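"""Per-condition time-to-contact table from the bundled dataset.

Prints each larva's time from container placement to first contact
(min:s) for four yeast concentrations, plus the per-condition mean -
the standard summary of how quickly larvae locate the stimulus.
"""

from larvasearch import summarize_time_to_contact, yeast_time_to_contact

table = summarize_time_to_contact(yeast_time_to_contact())
print(table.to_string())
print()
print("Times are min:s; blank cells pad conditions with fewer larvae.")
print("The 'mean' row is the arithmetic mean rounded to the nearest second.")
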