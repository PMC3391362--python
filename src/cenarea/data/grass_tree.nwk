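((('sorghum':0.00950939280685307413,('maize':0.00231520485691936832,'Z. luxurians':0.01052332533144828206):0.00367176807056998015):0.01041711803339982756,('foxtail millet':0.01363691334023187443,'pearl millet':0.01520671944747864317):0.01592780163032410726):0.02586075002500199532,(('oat':0.03072769607026095903,('barley':0.01983366653899813412,('rye':0.01449881409177665101,'wheat':0.00350123323061236674):0.00909150693055843159):0.02146457938246661493):0.01807421402216232917,'rice':0.04736460143268115403):0.00833952027397439483);
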