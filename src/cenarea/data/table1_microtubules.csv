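name,genome_size_mb,chromosome_number,total_centromere_area,microtubules_per_kinetochore
Schizosaccharomyces pombe,14.1,3,,3
Saccharomyces cerevisiae,12,16,,1
Candida albicans,16,8,,1
Drosophila,165,4,,5
Human,3000,23,,17
Fetal rats,2800,21,,7
CHO cells,3032,11,,12
PtK cells,3000,6,,24
Ostreococcus tauri,12.2,20,,0.4
Haemanthus,57213,8,,75
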