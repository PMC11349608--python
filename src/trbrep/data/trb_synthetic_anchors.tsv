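id	kind	anchor_nt
TRBV1	V	54
TRBV2	V	54
TRBV3-1	V	54
TRBV3-2	V	54
TRBV4-1	V	54
TRBV4-2	V	54
TRBV4-3	V	54
TRBV5-1	V	54
TRBV5-3	V	54
TRBV5-4	V	54
TRBV5-5	V	54
TRBV5-6	V	54
TRBV5-7	V	54
TRBV5-8	V	54
TRBV6-1	V	54
TRBV6-2	V	54
TRBV6-3	V	54
TRBV6-4	V	54
TRBV6-5	V	54
TRBV6-6	V	54
TRBV6-7	V	54
TRBV6-8	V	54
TRBV7-1	V	54
TRBV7-2	V	54
TRBV7-3	V	54
TRBV7-4	V	54
TRBV7-6	V	54
TRBV7-7	V	54
TRBV7-8	V	54
TRBV7-9	V	54
TRBV9	V	54
TRBV10-1	V	54
TRBV10-2	V	54
TRBV10-3	V	54
TRBV11-1	V	54
TRBV11-2	V	54
TRBV11-3	V	54
TRBV12-1	V	54
TRBV12-2	V	54
TRBV12-3	V	54
TRBV12-4	V	54
TRBV13	V	54
TRBV14	V	54
TRBV15	V	54
TRBV16	V	54
TRBV17	V	54
TRBV18	V	54
TRBV19	V	54
TRBV20-1	V	54
TRBV21-1	V	54
TRBV23-1	V	54
TRBV24-1	V	54
TRBV25-1	V	54
TRBV26	V	54
TRBV27	V	54
TRBV28	V	54
TRBV29-1	V	54
TRBV30	V	54
TRBD1	D	NA
TRBD2	D	NA
TRBJ1-1	J	9
TRBJ1-2	J	9
TRBJ1-3	J	9
TRBJ1-4	J	9
TRBJ1-5	J	9
TRBJ1-6	J	9
TRBJ2-1	J	9
TRBJ2-2	J	9
TRBJ2-3	J	9
TRBJ2-4	J	9
TRBJ2-5	J	9
TRBJ2-6	J	9
TRBJ2-7	J	9
TRBJ2-2p	J	9
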