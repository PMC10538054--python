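name,class,formula,tier
PC(34:1),PC,C42H82NO8P,tissue_specific
PC(32:0),PC,C40H80NO8P,tissue_specific
PC(32:2),PC,C40H76NO8P,tissue_specific
PC(32:3),PC,C40H74NO8P,tissue_specific
PC(32:4),PC,C40H72NO8P,tissue_specific
PC(36:2),PC,C44H84NO8P,tissue_specific
PE(31:3),PE,C36H66NO8P,tissue_specific
PE(32:1),PE,C37H72NO8P,tissue_specific
PE(32:4),PE,C37H66NO8P,tissue_specific
PE(38:7),PE,C43H72NO8P,tissue_specific
PE(40:2),PE,C45H86NO8P,tissue_specific
PE(40:6),PE,C45H78NO8P,tissue_specific
PE(40:7),PE,C45H76NO8P,tissue_specific
PI(38:4),PI,C47H83O13P,tissue_specific
PI(28:2),PI,C37H67O13P,tissue_specific
PI(40:2),PI,C49H91O13P,tissue_specific
PS(26:0),PS,C32H62NO10P,tissue_specific
SM(d32:1),SM,C37H75N2O6P,tissue_specific
SM(d33:0),SM,C38H79N2O6P,tissue_specific
SM(d33:1),SM,C38H77N2O6P,tissue_specific
SM(d34:1),SM,C39H79N2O6P,tissue_specific
SM(d35:1),SM,C40H81N2O6P,tissue_specific
SM(d36:0),SM,C41H85N2O6P,tissue_specific
SM(d36:1),SM,C41H83N2O6P,tissue_specific
SM(d36:3),SM,C41H79N2O6P,tissue_specific
SM(d38:2),SM,C43H85N2O6P,tissue_specific
SM(d41:2),SM,C46H91N2O6P,tissue_specific
SM(d42:0),SM,C47H97N2O6P,tissue_specific
SM(d42:1),SM,C47H95N2O6P,tissue_specific
SM(d42:2),SM,C47H93N2O6P,tissue_specific
LPC(3:0),LPC,C11H24NO7P,tissue_specific
LPC(4:0),LPC,C12H26NO7P,tissue_specific
LPC(5:0),LPC,C13H28NO7P,tissue_specific
LPC(16:0),LPC,C24H50NO7P,tissue_specific
LPC(18:1),LPC,C26H52NO7P,tissue_specific
LPE(17:2),LPE,C22H42NO7P,tissue_specific
LPE(20:5),LPE,C25H42NO7P,tissue_specific
LPE(22:4),LPE,C27H48NO7P,tissue_specific
LPE(22:5),LPE,C27H46NO7P,tissue_specific
LPI(18:0),LPI,C27H53O12P,tissue_specific
LPI(19:0),LPI,C28H55O12P,tissue_specific
LPI(20:5),LPI,C29H47O12P,tissue_specific
LPI(22:1),LPI,C31H59O12P,tissue_specific
LPI(22:2),LPI,C31H57O12P,tissue_specific
LPS(14:0),LPS,C20H40NO9P,tissue_specific
LPS(22:0),LPS,C28H56NO9P,tissue_specific
LPS(24:0),LPS,C30H60NO9P,tissue_specific
CE(17:1),CE,C44H76O2,tissue_specific
CE(18:0),CE,C45H80O2,tissue_specific
CE(19:0),CE,C46H82O2,tissue_specific
CE(20:0),CE,C47H84O2,tissue_specific
CE(20:1),CE,C47H82O2,tissue_specific
Cer(d42:1),Cer,C42H83NO3,tissue_specific
CAR(20:3),CAR,C27H47NO4,tissue_specific
PC(34:1),PC,C42H82NO8P,generic
PC(32:0),PC,C40H80NO8P,generic
PC(20:0),PC,C28H56NO8P,generic
PC(34:2),PC,C42H80NO8P,generic
PC(36:4),PC,C44H80NO8P,generic
PC(38:6),PC,C46H80NO8P,generic
PE(34:1),PE,C39H76NO8P,generic
PE(36:2),PE,C41H78NO8P,generic
SM(d34:1),SM,C39H79N2O6P,generic
SM(d40:1),SM,C45H91N2O6P,generic
LPC(18:0),LPC,C26H54NO7P,generic
LPE(18:1),LPE,C23H46NO7P,generic
PI(34:1),PI,C43H81O13P,generic
FA(22:6),FA,C22H32O2,generic
CAR(16:0),CAR,C23H45NO4,generic
Cer(d34:1),Cer,C34H67NO3,generic
phosphocholine,other,C5H14NO4P,generic
choline,other,C5H13NO,generic
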