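id,kind,structure,carbon_count,label,salt_form
amine-1,amine,NCCCN(C)C,5,3-(dimethylamino)-1-propylamine,False
amine-2,amine,CCCCN,4,butan-1-amine (monoamine; curator-transcribed synthetic stand-in),False
amine-3,amine,COCCCN,4,3-methoxypropan-1-amine (monoamine; curator-transcribed synthetic stand-in),False
amine-4,amine,CN(C)N,2,"1,1-dimethylhydrazine (hydrazine; curator-transcribed synthetic stand-in)",False
amine-5,amine,NN1CCCC1,4,1-aminopyrrolidine (hydrazine; curator-transcribed synthetic stand-in),False
amine-6,amine,CCCCCCN,6,hexan-1-amine (monoamine; curator-transcribed synthetic stand-in),False
amine-7,amine,NCCN(C)C,4,"N,N-dimethylethylenediamine (curator-transcribed synthetic stand-in)",False
amine-8,amine,NCCCCN(C)C,6,4-(dimethylamino)butan-1-amine (four-carbon spacer; curator-transcribed synthetic stand-in),False
amine-9,amine,NCCCN(CC)CC,7,3-(diethylamino)propan-1-amine (curator-transcribed synthetic stand-in),False
amine-10,amine,NCCN(CC)CC,6,2-(diethylamino)ethan-1-amine (curator-transcribed synthetic stand-in),False
amine-11,amine,NCCN1CCCC1,6,1-(2-aminoethyl)pyrrolidine (fixed by product formula C42H82N2O4),False
amine-12,amine,NCCCN1CCCC1,7,1-(3-aminopropyl)pyrrolidine (curator-transcribed synthetic stand-in),False
amine-13,amine,NCCN1CCOCC1,6,4-(2-aminoethyl)morpholine (curator-transcribed synthetic stand-in),False
amine-14,amine,NCCN1CCCCC1,7,1-(2-aminoethyl)piperidine (curator-transcribed synthetic stand-in),False
amine-15,amine,NCCN(C(C)C)C(C)C,8,"N,N-diisopropylethylenediamine (curator-transcribed synthetic stand-in)",False
amine-16,amine,CNCCNC,4,"N,N'-dimethylethylenediamine (di-secondary; curator-transcribed synthetic stand-in)",False
amine-17,amine,C1CNCCN1,4,piperazine (di-secondary; curator-transcribed synthetic stand-in),False
amine-18,amine,CNCCCNC,5,"N,N'-dimethyl-1,3-propanediamine (di-secondary; curator-transcribed synthetic stand-in)",False
amine-19,amine,CCNCCNCC,6,"N,N'-diethylethylenediamine (di-secondary; curator-transcribed synthetic stand-in)",False
amine-20,amine,C1CNCCNC1,5,"1,4-diazepane (di-secondary; curator-transcribed synthetic stand-in)",False
epoxide-6,epoxide,CCCCC1CO1,6,"1,2-epoxyhexane",False
epoxide-8,epoxide,CCCCCCC1CO1,8,"1,2-epoxyoctane",False
epoxide-10,epoxide,CCCCCCCCC1CO1,10,"1,2-epoxydecane",False
epoxide-12,epoxide,CCCCCCCCCCC1CO1,12,"1,2-epoxydodecane",False
epoxide-14,epoxide,CCCCCCCCCCCCC1CO1,14,"1,2-epoxytetradecane",False
acyl-6,acyl_chloride,CCCCCC(Cl)=O,6,hexanoyl chloride,False
acyl-8,acyl_chloride,CCCCCCCC(Cl)=O,8,octanoyl chloride,False
acyl-10,acyl_chloride,CCCCCCCCCC(Cl)=O,10,decanoyl chloride,False
acyl-12,acyl_chloride,CCCCCCCCCCCC(Cl)=O,12,dodecanoyl chloride,False
acyl-14,acyl_chloride,CCCCCCCCCCCCCC(Cl)=O,14,tetradecanoyl chloride,False
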