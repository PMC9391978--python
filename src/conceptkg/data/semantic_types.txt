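# Default UMLS semantic-type allowlist (26 neurodevelopmental-disorder-relevant
# types). One type per line; lines starting with '#' are ignored. Names are
# matched case-insensitively with whitespace collapsed and en dashes treated
# as hyphens.
activity
age group
behavior
congenital abnormality
diagnostic procedure
daily or recreational activity
disease or syndrome
educational activity
family group
finding
health care-related organization
health care activity
individual behavior
injury or poisoning
mental process
mental or behavioral dysfunction
occupational activity
occupation or discipline
organization
patient or disabled group
professional or occupational group
professional society
self-help or relief organization
social behavior
sign or symptom
therapeutic or preventive procedure
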